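"""Regenerate the shipped valid GC/BC populations via stochastic search.

Runs the MPMOSS rejection search at the default integration step and
stores the first 40 valid granule-cell and 20 valid basket-cell models
(with search metadata) under ``src/dgnet/data/``.  Takes a few minutes
on one CPU.
"""

import argparse
import pathlib
import sys
import time

from dgnet.mpmoss import (ValidationBounds, bc_parameter_table,
                          gc_parameter_table, run_search)
from dgnet.populations import save_population

DATA_DIR = pathlib.Path(__file__).resolve().parent.parent / "src" / "dgnet" / "data"


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--n-gc", type=int, default=4000)
    ap.add_argument("--n-bc", type=int, default=1500)
    ap.add_argument("--seed-gc", type=int, default=1001)
    ap.add_argument("--seed-bc", type=int, default=1002)
    ap.add_argument("--keep-gc", type=int, default=40)
    ap.add_argument("--keep-bc", type=int, default=20)
    args = ap.parse_args()

    DATA_DIR.mkdir(parents=True, exist_ok=True)
    for cls, table, n, seed, keep, fname in (
        ("GC", gc_parameter_table(), args.n_gc, args.seed_gc,
         args.keep_gc, "gc_population.json"),
        ("BC", bc_parameter_table(), args.n_bc, args.seed_bc,
         args.keep_bc, "bc_population.json"),
    ):
        t0 = time.time()
        pop = run_search(table, ValidationBounds.table1(cls), n, seed)
        print(f"{cls}: {len(pop)}/{n} valid ({100 * pop.yield_fraction:.2f}%) "
              f"in {time.time() - t0:.0f}s", file=sys.stderr)
        save_population(pop, DATA_DIR / fname, max_models=keep)


if __name__ == "__main__":
    main()
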