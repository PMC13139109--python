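"""Centrality-recovery experiment on the planted-hub truth: how reliably
does stage-1 guidance pick the planted most-central composite from fitted
baseline networks, as a function of baseline length?  Includes the
oracle path (scoring the generating matrix: exact by construction) and a
no-ordering null (recovery should sit at chance, 1/3).

Writes results/recovery/recovery_summary.csv.
"""

from pathlib import Path

import pandas as pd

from netguide.ema import default_registry
from netguide.synth import default_truth, recovery_experiment, uniform_truth

ROOT = Path(__file__).resolve().parent.parent / "results"
SEED = 20240905


def main() -> None:
    registry = default_registry()
    truth = default_truth(registry)
    out = ROOT / "recovery"
    out.mkdir(parents=True, exist_ok=True)
    rows = []

    oracle = recovery_experiment(n_replicates=10, occasions=150, seed=SEED,
                                 truth=truth, use_truth_matrix=True)
    rows.append({"condition": "generating matrix (oracle)", "occasions": 150,
                 **{k: oracle[k] for k in ("mcni_recovery_rate",
                                           "lcni_recovery_rate", "mean_concordance")}})
    for occasions, n_rep in ((150, 40), (600, 20)):
        r = recovery_experiment(n_replicates=n_rep, occasions=occasions,
                                seed=SEED + occasions, truth=truth)
        rows.append({"condition": f"fitted ({n_rep} replicates)",
                     "occasions": occasions,
                     **{k: r[k] for k in ("mcni_recovery_rate",
                                          "lcni_recovery_rate", "mean_concordance")}})
    null = recovery_experiment(n_replicates=24, occasions=150, seed=SEED + 7,
                               truth=uniform_truth(registry))
    rows.append({"condition": "no-ordering null", "occasions": 150,
                 **{k: null[k] for k in ("mcni_recovery_rate",
                                         "lcni_recovery_rate", "mean_concordance")}})
    table = pd.DataFrame(rows).round(3)
    table.to_csv(out / "recovery_summary.csv", index=False)
    print(table.to_string(index=False))
    print("\nOracle scoring is exact; fitted recovery improves with baseline "
          "length; the null sits near chance (1/3).")


if __name__ == "__main__":
    main()
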