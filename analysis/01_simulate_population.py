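#!/usr/bin/env python
"""Generate the synthetic strain population used by the downstream analyses.

Writes a 12-strain population (monokaryons and dikaryons, HD + P/R loci,
planted decoy ORFs) with its truth tables to scratch/population/.
"""

import argparse
from pathlib import Path

from matloci import synthetic

ROOT = Path(__file__).resolve().parent.parent


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=2083)
    ap.add_argument("--n-strains", type=int, default=12)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "population")
    args = ap.parse_args()

    specs = synthetic.random_specs(args.n_strains, seed=args.seed)
    table, _ = synthetic.generate_population(specs, args.out, seed=args.seed)
    n_di = (table.karyotype == "di").sum()
    print(f"wrote {len(table)} strains ({n_di} dikaryons, {len(table) - n_di} monokaryons)")
    print(f"truth tables under {args.out}")
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
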