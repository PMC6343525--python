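#!/usr/bin/env python
"""Estimate drought response parameters and compare sampling designs.

Generates stressed/control plant pairs on the platform's forward model
for the four contrasting genotypes, normalizes stressed transpiration by
the same-day control mean, fits the FTSW response curve per genotype,
and contrasts the parameter precision of dense daily dry-down coverage
against sparse three-visit sampling.  Writes:

    results/response_parameters.csv   a_hat, se per genotype
    results/design_precision.csv      mean se(a) dense vs sparse
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from heliastress.cropsim import TABLE_GENOTYPES
from heliastress.experiments import design_precision
from heliastress.traits import fit_ftsw_response, simulate_response_points

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 1):
    rng = np.random.default_rng(seed)
    OUT.mkdir(exist_ok=True)

    # daily dry-down coverage, 12 plants x ~ the stress window
    rows = []
    for g in TABLE_GENOTYPES:
        for trait, a_true in (("TR", g.a_tr), ("LE", g.a_le)):
            pts = simulate_response_points(
                a_true, np.tile(np.linspace(0.03, 1.0, 25), 3), 0.05, rng
            )
            fit = fit_ftsw_response(pts, trait=trait)
            rows.append((g.name, trait, a_true, fit.a_hat, fit.se_a, fit.n_points))
    params = pd.DataFrame(
        rows, columns=["genotype", "trait", "a_true", "a_hat", "se_a", "n_points"]
    )
    params.to_csv(OUT / "response_parameters.csv", index=False)
    print("Fitted response parameters (truth in parentheses):")
    for _, r in params.iterrows():
        print(f"  {r.genotype:12s} {r.trait}: {r.a_hat:7.2f} +/- {r.se_a:.2f}"
              f"  ({r.a_true})")

    dp = design_precision(n_reps=50, seed=seed)
    dp.to_csv(OUT / "design_precision.csv", index=False)
    wide = dp.pivot_table(index="a_true", columns="design", values="mean_se_a")
    print("\nMean se(a), dense daily coverage vs sparse 3-visit sampling:")
    print(wide.to_string())
    print("Dense coverage gives the smaller parameter error for every genotype."
          if (wide["dense"] < wide["sparse"]).all()
          else "WARNING: dense coverage did not dominate.")


if __name__ == "__main__":
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    main(ap.parse_args().seed)
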