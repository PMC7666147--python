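"""Deterministic stress scenarios: growth rates and reductions vs control.

Runs the seven-scenario set through the three-stage Leslie matrix model and
prints the growth table.  The headline result: combined male+female larval
dehydration cuts log population growth by ~21%, gel removal by ~13%, and
thermal stress on eggs by ~8%; no single stressor pushes lambda below 1.
The worst-case combination is also compared against the originally reported
declining value (lambda = 0.95), which the reconstructed matrix does not
recover.
"""

import argparse
import json
from pathlib import Path

from midgepop.scenarios import (
    run_scenarios,
    report_table,
    study_scenarios,
    worst_case_discrepancy,
)


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", type=Path, default=Path("results/scenarios.csv"))
    args = ap.parse_args()

    results = run_scenarios(study_scenarios())
    table, meta = report_table(results, rounding=True)
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {args.out}")

    d = worst_case_discrepancy()
    print(f"\nworst case: computed lambda {d['computed_lambda']:.3f} "
          f"(growing) vs reported {d['reported_lambda']} (declining); "
          f"the reported value is not recoverable from the tabulated rates")
    (args.out.parent / "worst_case_discrepancy.json").write_text(
        json.dumps(d, indent=2)
    )


if __name__ == "__main__":
    main()
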