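"""Backcrossed-RIL marker panel generator.

Each line is a recombinant inbred line crossed back to the recurrent
parent, so a marker shows only two states: homozygous for the recurrent
parent (0) or heterozygous (1).  Along each linkage group the calls
follow a two-state Markov chain whose switch probability between
adjacent markers is the Haldane recombination fraction
r = 0.5 * (1 - exp(-2 d)) for map distance d in Morgans.  A configurable
fraction of markers are exact copies of their left neighbour, creating
the redundancy that marker binning removes; the planted bin structure is
returned as ground truth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from heliastress.genotypes import MISSING, GenotypeMatrix

__all__ = ["gen_ril_panel", "haldane"]

BP_PER_CM = 1_000_000  # synthetic map: 1 cM per Mb


def haldane(d_morgan):
    """Haldane map function: recombination fraction for distance in Morgans."""
    return 0.5 * (1.0 - np.exp(-2.0 * np.asarray(d_morgan, dtype=float)))


def gen_ril_panel(
    n_lines: int,
    lg_count: int = 17,
    markers_per_lg: int = 20,
    dup_fraction: float = 0.0,
    lg_length_cm: float = 100.0,
    missing_rate: float = 0.0,
    parent_bad_fraction: float = 0.0,
    seed: int = 0,
):
    """Generate a biallelic backcross panel with map, parent table and truth.

    Returns
    -------
    geno : GenotypeMatrix
        Calls over {0, 1} (plus MISSING at ``missing_rate``), markers in
        (linkage_group, pos_bp) order.
    parents : DataFrame
        Per-marker ``het_or_missing_rate`` observed when assaying the
        recurrent parent; ``parent_bad_fraction`` of markers are given a
        rate above the 10% filter threshold.
    truth : dict
        ``bin_id`` per marker (markers copied from a neighbour share its
        bin) and ``duplicated`` boolean mask.
    """
    if n_lines < 2:
        raise ValueError("n_lines must be >= 2")
    if markers_per_lg < 2:
        raise ValueError("markers_per_lg must be >= 2")
    if not (0.0 <= dup_fraction <= 1.0):
        raise ValueError(f"dup_fraction must be in [0, 1], got {dup_fraction}")
    rng = np.random.default_rng(seed)

    blocks, rows = [], []
    for lg in range(1, lg_count + 1):
        pos_cm = np.sort(rng.uniform(0.0, lg_length_cm, size=markers_per_lg))
        r = haldane(np.diff(pos_cm) / 100.0)
        calls = np.empty((markers_per_lg, n_lines), dtype=np.int8)
        calls[0] = rng.random(n_lines) < 0.5
        for k in range(1, markers_per_lg):
            flip = rng.random(n_lines) < r[k - 1]
            calls[k] = np.where(flip, 1 - calls[k - 1], calls[k - 1])
        blocks.append(calls)
        for k in range(markers_per_lg):
            rows.append((f"M{lg:02d}_{k:03d}", lg, int(round(pos_cm[k] * BP_PER_CM))))

    calls = np.vstack(blocks)
    map_df = pd.DataFrame(rows, columns=["marker", "linkage_group", "pos_bp"])
    m = len(map_df)

    # plant exact duplicates of the left neighbour (never the first of a group)
    bin_id = np.arange(m)
    duplicated = np.zeros(m, dtype=bool)
    eligible = np.flatnonzero(map_df["linkage_group"].diff().fillna(1).to_numpy() == 0)
    n_dup = int(round(dup_fraction * m))
    if n_dup > 0 and eligible.size > 0:
        chosen = rng.choice(eligible, size=min(n_dup, eligible.size), replace=False)
        for i in np.sort(chosen):
            calls[i] = calls[i - 1]
            bin_id[i] = bin_id[i - 1]
            duplicated[i] = True

    if missing_rate > 0:
        mask = rng.random(calls.shape) < missing_rate
        calls = np.where(mask, MISSING, calls).astype(np.int8)

    parent_rate = np.abs(rng.normal(0.0, 0.01, size=m))
    n_bad = int(round(parent_bad_fraction * m))
    if n_bad > 0:
        bad = rng.choice(m, size=n_bad, replace=False)
        parent_rate[bad] = rng.uniform(0.12, 0.5, size=n_bad)
    parents = pd.DataFrame(
        {"marker": map_df["marker"], "het_or_missing_rate": parent_rate}
    )

    geno = GenotypeMatrix(
        calls=calls,
        map=map_df,
        line_ids=[f"RIL{i:04d}" for i in range(n_lines)],
    )
    truth = {"bin_id": bin_id, "duplicated": duplicated}
    return geno, parents, truth
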