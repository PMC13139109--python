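"""Retrospective alternative-guidance grid: for a subset of participants,
which node would each alternative matching procedure have targeted?

Methods span CT-VAR TEC/IEC point estimates (4- and 7-variable networks),
smaller delta-times, strongest lagged path to interference, penalized and
unpenalized DT contemporaneous networks with strength / expected
influence / betweenness / closeness centralities, and the descriptive
candidates (highest baseline facet mean, strongest baseline correlation
with each outcome).  Individual method failures become NA cells.

Writes results/alternative_guidance/<participant>_grid.csv.
"""

from pathlib import Path

import pandas as pd

from netguide.ema import EMASeries, default_registry, read_ema
from netguide.guidance import GuidanceConfig, alternative_guidance_grid

ROOT = Path(__file__).resolve().parent.parent / "results"
SUBSET = ("P2", "P3", "P6")  # participants examined retrospectively


def main() -> None:
    registry = default_registry()
    out = ROOT / "alternative_guidance"
    out.mkdir(parents=True, exist_ok=True)
    cfg = GuidanceConfig(measurement_noise="zero", maxiter=250)
    frames = {}
    for path in sorted((ROOT / "data").glob("participant_*.csv")):
        if "truth" in path.name:
            continue
        series = read_ema(path, registry)
        if series.participant not in SUBSET:
            continue
        mask = (series.phase == "baseline").to_numpy()
        baseline = EMASeries(series.participant, series.data.loc[mask],
                             series.phase.loc[mask])
        grid = alternative_guidance_grid(baseline, registry, cfg)
        grid.to_csv(out / f"{series.participant}_grid.csv", index=False)
        frames[series.participant] = grid.set_index("method")["selected"]
    wide = pd.DataFrame(frames)
    wide.to_csv(out / "grid_all.csv")
    print("Selected node per alternative guidance method:")
    print(wide.to_string())
    n_na = int(wide.isna().sum().sum())
    print(f"\n{n_na} method/participant cells were NA (isolated method failures).")


if __name__ == "__main__":
    main()
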