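"""Generate the synthetic study inputs.

Writes the array-card Ct table (4 cell lines x {21%, 0.2%, 1%} O2 x
triplicates), the 400-patient development cohort (anchor mRNA + miRNA
matrices, OS/PFS survival) and the 190-patient two-arm trial, together with
the planted ground truth, under results/inputs/.
"""

import sys
from pathlib import Path

from hypomir import SimulationConfig
from hypomir import io as hio
from hypomir.simulate import generate_cohort, generate_ct_table, generate_trial

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/inputs")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)

    ct, ct_truth = generate_ct_table(cfg)
    hio.write_ct_table(ct, OUT / "ct_table.csv")
    ct_truth.to_json(OUT / "ct_ground_truth.json")
    n_planted = len(ct_truth.planted_induced)
    print(f"Ct table: {ct['cell_line'].nunique()} lines, "
          f"{(ct['feature_class'] == 'target').sum() // ct[['cell_line', 'o2_percent', 'replicate']].drop_duplicates().shape[0]} targets/sample, "
          f"{n_planted} features planted as hypoxia-induced")

    mrna, mirna, surv, truth = generate_cohort(cfg)
    hio.write_expression_matrix(mrna, OUT / "cohort_mrna.tsv")
    hio.write_expression_matrix(mirna, OUT / "cohort_mirna.tsv")
    hio.write_survival_table(surv, OUT / "cohort_survival.csv")
    truth.to_json(OUT / "cohort_ground_truth.json")
    print(f"cohort: n={len(mrna)}, {int(truth.latent_hypoxia.sum())} hypoxic, "
          f"planted signature {len(truth.signature_positive)}+ / "
          f"{len(truth.signature_negative)}-")

    t_mirna, t_surv, t_truth = generate_trial(cfg)
    hio.write_expression_matrix(t_mirna, OUT / "trial_mirna.tsv")
    hio.write_survival_table(t_surv, OUT / "trial_survival.csv")
    t_truth.to_json(OUT / "trial_ground_truth.json")
    arms = t_surv[t_surv["endpoint"] == "OS"]["arm"].value_counts().to_dict()
    print(f"trial: arms {arms}, {int(t_truth.latent_hypoxia.sum())} hypoxic")


if __name__ == "__main__":
    main()
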