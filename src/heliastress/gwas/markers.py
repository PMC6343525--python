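"""Marker quality filtering and redundancy binning.

Filtering keeps markers that are clean in the recurrent parent (less
than 10% heterozygous or missing calls) and segregate near the expected
backcross ratio (heterozygote frequency between 40 and 60%).  Binning
merges markers with identical segregation patterns into genetic bins and
keeps one representative per bin, the left-most on the map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from heliastress.genotypes import MISSING, GenotypeMatrix

__all__ = ["FilterReport", "filter_markers", "bin_markers"]


@dataclass(frozen=True)
class FilterReport:
    n_input: int
    n_kept: int
    n_parent_het_missing: int
    n_freq_out_of_range: int


def filter_markers(
    geno: GenotypeMatrix,
    parents: pd.DataFrame,
    het_max: float = 0.10,
    freq_range: tuple[float, float] = (0.40, 0.60),
) -> tuple[GenotypeMatrix, FilterReport]:
    """Keep markers clean in the parent and near-balanced in the population.

    ``parents`` carries one ``het_or_missing_rate`` per marker (fraction of
    heterozygous-or-missing calls observed when assaying the recurrent
    parent).  Rejection counts per reason are reported; a marker failing
    both rules is counted under both.
    """
    if not (0.0 < het_max < 1.0) or not (0.0 < freq_range[0] < freq_range[1] < 1.0):
        raise ValueError("thresholds must lie in (0, 1)")
    rate = (
        parents.set_index("marker")["het_or_missing_rate"]
        .reindex(geno.map["marker"])
        .to_numpy()
    )
    parent_fail = ~(rate < het_max)
    freq = geno.frequencies()
    freq_fail = (freq < freq_range[0]) | (freq > freq_range[1])
    keep = ~(parent_fail | freq_fail)
    report = FilterReport(
        n_input=geno.n_markers,
        n_kept=int(keep.sum()),
        n_parent_het_missing=int(parent_fail.sum()),
        n_freq_out_of_range=int(freq_fail.sum()),
    )
    if report.n_kept == 0:
        warnings.warn("all markers rejected by the quality filters", stacklevel=2)
    return geno.subset_markers(np.flatnonzero(keep)), report


def bin_markers(
    geno: GenotypeMatrix,
    missing_wildcard: bool = False,
) -> tuple[pd.Series, GenotypeMatrix]:
    """Group markers with identical call vectors into bins.

    By default missing calls must match exactly; with
    ``missing_wildcard=True`` a missing call is compatible with either
    state and markers join (greedily, in map order) the first bin whose
    representative they are compatible with.

    Returns (bins, representatives): a marker-indexed Series of bin ids
    and the panel reduced to one representative per bin (the left-most
    marker by (linkage_group, pos_bp)).
    """
    order = np.lexsort((geno.map["pos_bp"].to_numpy(),
                        geno.map["linkage_group"].to_numpy()))
    calls = geno.calls
    bin_of = np.empty(geno.n_markers, dtype=int)
    if not missing_wildcard:
        seen: dict[bytes, int] = {}
        reps = []
        for i in order:
            key = calls[i].tobytes()
            if key not in seen:
                seen[key] = len(reps)
                reps.append(i)
            bin_of[i] = seen[key]
    else:
        reps = []
        for i in order:
            row = calls[i]
            for b, j in enumerate(reps):
                ref = calls[j]
                ok = (row == ref) | (row == MISSING) | (ref == MISSING)
                if ok.all():
                    bin_of[i] = b
                    break
            else:
                bin_of[i] = len(reps)
                reps.append(i)
    bins = pd.Series(bin_of, index=geno.marker_ids, name="bin")
    return bins, geno.subset_markers(np.sort(reps))
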