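"""Consolidate the raw workshop factor lists into the main-factor set.

Applies the packaged keep/merge/split/exclude mapping to the 30 raw
factors named across the two elicitation workshops and writes the
resulting main-factor table.  Finding: the 16 scientists' and 14
practitioners' raw factors consolidate into 11 main risk factors; 7 raw
factors are excluded as ambiguous, redundant, or not clearly
post-migration.
"""

from pathlib import Path

from panelfcm import apply_consolidation, validate_mapping
from panelfcm import io as pio

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    raw = pio.load_workshop_factors()
    mapping = pio.load_consolidation_mapping()
    report = validate_mapping(raw, mapping)
    assert report.ok, report.summary()
    mains = apply_consolidation(raw, mapping)

    by_panel = {}
    for r in raw:
        by_panel.setdefault(r.source_panel, []).append(r)
    excluded = [r.label for a in mapping if a.action == "exclude"
                for r in a.raw_labels]

    out = RESULTS / "main_factors.csv"
    with open(out, "w") as fh:
        fh.write("id,name,description\n")
        for m in mains:
            fh.write(f"{m.id},{m.name},\"{m.description}\"\n")

    print(f"raw factors: {len(by_panel['scientists'])} (scientists) + "
          f"{len(by_panel['practitioners'])} (practitioners) = {len(raw)}")
    print(f"excluded raw factors: {len(excluded)} ({', '.join(sorted(set(excluded)))})")
    print(f"main factors of the final system model: {len(mains)} -> {out}")
    for m in mains:
        print(f"  {m.id:26s} {m.name}")


if __name__ == "__main__":
    main()
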