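#!/usr/bin/env python
"""Assign elemental formulas to the selected channels and verify isotopes.

For every channel retained by the selection funnel, enumerates CHNOS
formulas within 5 mTh of the protonated mass, then checks 13C isotopologue
support: where a companion channel 1.003355 Th higher was also retained, the
observed (M+1)/M net-concentration ratio is compared with the top
candidate's expectation.  Writes ranked candidates with mass errors, RDBE
and expected M+1 ratios.
"""

import argparse
import json
from pathlib import Path

from ptrvoc.formulas import C13_MINUS_C12, check_isotope_support, enumerate_formulas
from ptrvoc.reduction import reduce_run
from ptrvoc.selection import run_selection
from ptrvoc.synthetic import default_scenario, generate_experiment


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--tol-mda", type=float, default=5.0)
    parser.add_argument("--out", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    scenario = default_scenario(seed=args.seed)
    runs = generate_experiment(scenario)
    result = run_selection(runs)
    # net concentrations from the first fungal replicate, for the isotope check
    first_fungal = next(r for r in runs if r.category == "fungal")
    net = reduce_run(first_fungal).table["net_conc"]

    report = {}
    retained = set(result.retained_ids)
    for cid in result.retained_ids:
        mz = float(cid)
        candidates = enumerate_formulas(mz, args.tol_mda)
        entry = {
            "mz": mz,
            "candidates": [
                {
                    "formula": c.formula or "(bare proton)",
                    "theoretical_mz": c.theoretical_mz,
                    "error_mda": round(c.error_mda, 3),
                    "rdbe": c.rdbe,
                    "expected_m1_ratio": round(c.expected_m1_ratio, 4),
                }
                for c in candidates[:5]
            ],
        }
        iso_cid = f"{mz + C13_MINUS_C12:.3f}"
        if candidates and iso_cid in retained:
            supported, observed = check_isotope_support(
                float(net[cid]), float(net[iso_cid]), candidates[0], rel_tolerance=0.15
            )
            entry["isotope_check"] = {
                "plus1_channel": iso_cid,
                "observed_ratio": round(observed, 4),
                "supports_top_candidate": bool(supported),
            }
        report[cid] = entry

    with open(args.out / "formula_assignments.json", "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)

    for cid, entry in report.items():
        top = entry["candidates"][0]["formula"] if entry["candidates"] else "none"
        iso = entry.get("isotope_check", {})
        tag = f" [M+1 at {iso['plus1_channel']}: observed {iso['observed_ratio']}]" if iso else ""
        print(f"m/z {cid}: top candidate {top}{tag}")
    print(f"wrote {args.out}/formula_assignments.json")


if __name__ == "__main__":
    main()
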