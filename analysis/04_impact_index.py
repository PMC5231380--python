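"""The 0-4 conflict impact index per district, with its weight histogram.

One point per WORSE flag across {IMR rate, IMR endpoint, MMR rate,
MMR endpoint}; districts with a wholly unassessable indicator are not
scored.  The recomputed histogram is printed next to the published one
(they differ — the published summary tables do not reproduce their own
histogram, a known internal inconsistency that is surfaced, not patched).
Writes results/impact_index.csv.
"""

from collections import Counter
from pathlib import Path

from warhealth.fixtures import load_fixture
from warhealth.io import write_results
from warhealth.replicate import impact_index

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    records = impact_index()
    OUT.mkdir(exist_ok=True)
    rows = [
        {
            "unit_id": r.unit_id,
            "weight": "N/A" if r.weight is None else r.weight,
            **{k: v.value for k, v in r.components.items()},
        }
        for r in records
    ]
    write_results(
        rows,
        OUT / "impact_index.csv",
        columns=("unit_id", "weight", "imr_rate", "imr_endpoint",
                 "mmr_rate", "mmr_endpoint"),
    )
    hist = Counter("N/A" if r.weight is None else str(r.weight) for r in records)
    published = {
        str(k): v
        for k, v in load_fixture("table9").set_index("weight")["n_districts"].items()
    }
    print("weight  recomputed  published")
    for key in ("N/A", "0", "1", "2", "3", "4"):
        print(f"{key:>6}  {hist.get(key, 0):>10}  {published.get(key, 0):>9}")
    worst = sorted(r.unit_id for r in records if r.weight == 4)
    print(f"highest-impact districts (weight 4): {', '.join(worst)}")
    print(f"wrote {OUT / 'impact_index.csv'}")


if __name__ == "__main__":
    main()
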