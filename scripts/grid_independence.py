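#!/usr/bin/env python
"""Grid-independence study for scenario 1 (long-running tier).

Runs the scenario-1 naive treatment on successively refined grids, up to
N=256 intervals (~15 min on one core), and prints the healthy-damage
percentage per grid so the refinement trend can be inspected.

Usage:  python scripts/grid_independence.py [--grids 64,128,256]
"""

from __future__ import annotations

import argparse
import sys
import time

import nanotherm as nt


def main(argv=None) -> int:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--grids", default="64,128,256")
    args = parser.parse_args(argv)

    previous = None
    for N in (int(g) for g in args.grids.split(",")):
        cfg = nt.builtin_scenario(1, N=N)
        sc = nt.build_scenario(cfg)
        t0 = time.perf_counter()
        report = nt.evaluate_injections(sc, nt.naive_injection_points(cfg))
        nh = report.healthy_damage_pct
        delta = "" if previous is None else f"  (change {nh - previous:+.4f})"
        print(
            f"N={N:4d}: healthy damage {nh:.4f}%  tumor {report.tumor_damage_pct:.2f}%"
            f"{delta}  [{time.perf_counter() - t0:.0f} s]"
        )
        previous = nh
    return 0


if __name__ == "__main__":
    sys.exit(main())
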