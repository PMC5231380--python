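"""District infant-mortality classification from the packaged raw columns.

Classifies all 25 districts (rate flag, endpoint flag, label), tallies the
headline counts, and reconciles computed labels against the published
summary table.  Writes results/district_imr_classification.csv.
"""

from pathlib import Path

from warhealth.io import write_results
from warhealth.replicate import imr_classifications, imr_printed, imr_tally
from warhealth.classify import reconcile_labels

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    classifications = imr_classifications()
    OUT.mkdir(exist_ok=True)
    write_results(
        classifications,
        OUT / "district_imr_classification.csv",
        columns=("unit_id", "indicator", "rate_flag", "endpoint_flag", "label"),
    )
    t = imr_tally()
    print(
        f"IMR endpoint worse than counterfactual in {t.endpoint_worse['IMR']} "
        f"districts, {t.endpoint_worse_outside_conflict['IMR']} of them outside "
        f"the high-conflict zone; improvement slowed in {t.rate_worse['IMR']}."
    )
    diffs = reconcile_labels(classifications, imr_printed())
    for d in diffs:
        print(
            f"label disagreement {d.unit_id}: computed '{d.computed}' "
            f"vs published '{d.printed}'"
        )
    print(f"wrote {OUT / 'district_imr_classification.csv'}")


if __name__ == "__main__":
    main()
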