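#!/usr/bin/env python
"""Simulate the respiration bias induced by lognormal activity heterogeneity.

Runs the Monte-Carlo bias surface: mean Michaelis-Menten respiration of a
mean-matched lognormal population relative to the Gaussian baseline (the
index IR), over half-saturation constants Km in 1e2-1e5 and log-sd sigma in
0.01-3.5. The mean-field overestimate (1 - IR) grows with sigma and with Km,
peaking near 88% at the high-skew, high-Km corner — the "ignoring
heterogeneity can bias respiration by more than half" headline.
"""

import argparse
from pathlib import Path

from cellskew.core_io import write_results
from cellskew.resp_sim import SimConfig, bias_surface, quadrature_bias


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--n", type=int, default=100_000,
                    help="cells per grid cell (1e6 reproduces the full-scale run)")
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    config = SimConfig(n=args.n, seed=args.seed)
    surface = bias_surface(config)
    write_results(surface.table, args.out / "bias_surface.csv")

    peak = surface.table.loc[surface.table["pct_bias"].idxmax()]
    oracle = 100.0 * (1.0 - quadrature_bias(config.mu, config.cv, peak.sigma,
                                            config.rmax, peak.km, floor=config.floor))
    print(f"grid: {len(config.km_values)} Km x {len(config.sigma_values)} sigma, "
          f"{args.n:,} cells per cell")
    print(f"max percent bias {surface.max_pct_bias:.1f}% at Km={peak.km:.0f}, "
          f"sigma={peak.sigma} (quadrature oracle {oracle:.1f}%)")


if __name__ == "__main__":
    main()
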