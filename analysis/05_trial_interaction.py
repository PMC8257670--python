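"""Predictive validation in the simulated two-arm trial.

Scores the trial with the derived signature, stratifies at the upper
quartile, and asks the predictive questions: does the experimental arm
(RT+CON) lower the hazard within the hypoxic stratum but not the normoxic
one, is the treatment-by-hypoxia interaction significant, and do the
IHC-like hypoxia markers (CAIX, GLUT1, HIF1A) track the signature's calls?
"""

import sys
from pathlib import Path

from hypomir import RunConfig
from hypomir.pipeline import run_derivation, run_validation

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/validation")


def main() -> None:
    cfg = RunConfig(seed=SEED)
    derivation = run_derivation(cfg, outdir=None, write_plots=False)
    validation = run_validation(cfg, derivation.signature, derivation, outdir=OUT)

    cols = ["analysis", "endpoint", "term", "HR", "CI_low", "CI_high", "p"]
    print("trial analyses (upper-quartile stratification):")
    print(validation.trial_fits[cols].round(3).to_string(index=False))
    for ep, p in validation.interaction_p.items():
        print(f"interaction LRT p ({ep}): {p:.3g}")
    print("marker associations (Mann-Whitney, hypoxic vs normoxic calls):")
    print(validation.marker_tests.to_string(index=False,
                                            float_format=lambda v: f"{v:.3g}"))


if __name__ == "__main__":
    main()
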