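"""Cross-index comparison of direct effects and well-estimated flags.

Collects the manifests written by 03 (one or more runs), tabulates the
direct hazard ratio per SD of each deprivation index with its credible
interval, direction annotation, and well-estimated flag, and writes the
comparison table.
"""

import argparse
from pathlib import Path

from depmed import compare_runs


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("manifests", nargs="*",
                    default=["results/fits/manifest.json"] * 2)
    ap.add_argument("--out", type=Path, default=Path("results/comparison.csv"))
    args = ap.parse_args()

    table = compare_runs(list(args.manifests))
    args.out.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(args.out, index=False)
    print(table.to_string(index=False))
    print(f"\nwrote {args.out}")
    well = table[table.well_estimated]
    if len(well):
        print("well-estimated direct effects: "
              + ", ".join(sorted(set(well.exposure))))


if __name__ == "__main__":
    main()
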