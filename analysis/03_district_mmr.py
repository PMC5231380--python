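"""District maternal-mortality classification and headline tallies.

The headline MMR counts come from the published interpretation labels (the
raw columns disagree with the labels for two districts — both paths are
computed and the disagreements printed).  Writes
results/district_mmr_classification.csv.
"""

from pathlib import Path

from warhealth.io import write_results
from warhealth.replicate import (
    label_reconciliation,
    mmr_classifications,
    mmr_label_tally,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    classifications = mmr_classifications()
    OUT.mkdir(exist_ok=True)
    write_results(
        classifications,
        OUT / "district_mmr_classification.csv",
        columns=("unit_id", "indicator", "rate_flag", "endpoint_flag", "label"),
    )
    t = mmr_label_tally()
    print(
        f"MMR endpoint worse than counterfactual in {t.endpoint_worse['MMR']} "
        f"districts, {t.endpoint_worse_outside_conflict['MMR']} outside the "
        f"high-conflict zone; rate slowed without a worse endpoint in "
        f"{t.rate_worse_endpoint_not_worse['MMR']}."
    )
    for d in label_reconciliation()["MMR"]:
        print(
            f"label disagreement {d.unit_id}: computed '{d.computed}' "
            f"vs published '{d.printed}'"
        )
    print(f"wrote {OUT / 'district_mmr_classification.csv'}")


if __name__ == "__main__":
    main()
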