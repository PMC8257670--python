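"""Derive the signed miRNA hypoxia signature on the training cohort.

Anchor-signature median classification labels the cohort hypoxic/normoxic; a
stratified 70:30 split defines the training set; the shadow-feature (Boruta)
selector screens the seed miRNAs against those labels; the Spearman/BH filter
against the continuous anchor scores fixes membership and signs.  Writes the
signature (GMT + JSON), the Boruta decision table/plot and the correlation
table under results/signature/.
"""

import sys
from pathlib import Path

from hypomir import RunConfig
from hypomir.pipeline import run_derivation

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/signature")


def main() -> None:
    cfg = RunConfig(seed=SEED)
    d = run_derivation(cfg, outdir=OUT)
    sig, truth = d.signature, d.truth
    br = d.report.boruta_result
    print(f"training split: {len(d.train_ids)} train / {len(d.test_ids)} test")
    print(f"seed features: {len(d.seeds)}; after unexpressed filter: "
          f"{len(d.report.kept_seed_features)}")
    print(f"boruta ({br.iterations_run} iterations): {len(br.confirmed)} confirmed, "
          f"{len(br.tentative)} tentative, {len(br.rejected)} rejected")
    print(f"signature: {len(sig.positive)} positive / {len(sig.negative)} negative")
    correct = (len(set(sig.positive) & set(truth.signature_positive))
               + len(set(sig.negative) & set(truth.signature_negative)))
    extra = set(sig.features) - set(truth.signature_features)
    print(f"recovery vs planted 14-feature truth: {correct}/14 correct sign, "
          f"{len(extra)} false members")


if __name__ == "__main__":
    main()
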