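"""Genotype calling from per-sample allele read counts.

A biallelic SNP locus in an autotetraploid carries 0-4 copies of allele A1,
so true allelic ratios RC_A1/(RC_A1+RC_A2) fall near the quarters
0, 1/4, 1/2, 3/4, 1 (dosage classes 0|4 .. 4|0).  With shallow sequencing the
observed ratio is a noisy binomial estimate, and two deterministic rules are
applied before any call:

* the one-read rule - an allele supported by exactly one read is treated as
  absent (its count is zeroed), and
* ratio thresholds - a sample is homozygous when the ratio is <= 0.1 or
  >= 0.9 and heterozygous strictly in between; a zero effective total is a
  missing call.

Diploid calls collapse the three heterozygous dosage classes into a single
"H" class, which is the calling mode that survives shallow coverage.

All operations are exposed both as scalars and as vectorized numpy kernels;
the integer codes used throughout the package are ``HOM_A2=0, HET=1,
HOM_A1=2, MISSING=-1`` (the diploid code doubles as a count of A1 alleles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

# Diploid call codes: the non-missing codes count A1 alleles in a diploid
# reading, which structure.encode() relies on.
HOM_A2 = 0
HET = 1
HOM_A1 = 2
MISSING = -1

#: Tetraploid dosage codes are the A1 copy number 0..4; missing is -1.
TETRA_MISSING = -1

DIPLOID_LABELS = {HOM_A1: "A1", HET: "H", HOM_A2: "A2", MISSING: "N"}
TETRA_LABELS = {0: "0|4", 1: "1|3", 2: "2|2", 3: "3|1", 4: "4|0", TETRA_MISSING: "N"}

HET_LOW = 0.1   # ratio <= HET_LOW  -> homozygous A2
HET_HIGH = 0.9  # ratio >= HET_HIGH -> homozygous A1


@dataclass(frozen=True)
class GenotypeCall:
    """One sample-locus call: diploid class, tetraploid dosage, ratio."""

    diploid: int
    tetraploid: int
    ratio: float  # NaN when the effective total is zero

    @property
    def diploid_label(self) -> str:
        return DIPLOID_LABELS[self.diploid]

    @property
    def tetraploid_label(self) -> str:
        return TETRA_LABELS[self.tetraploid]


def one_read_rule(rc_a1, rc_a2):
    """Zero any allele count that is exactly 1 (single reads are noise).

    Accepts scalars or numpy arrays; returns the same shape.
    """
    a1 = np.asarray(rc_a1)
    a2 = np.asarray(rc_a2)
    if np.any(a1 < 0) or np.any(a2 < 0):
        raise ValueError("read counts must be non-negative")
    a1 = np.where(a1 == 1, 0, a1)
    a2 = np.where(a2 == 1, 0, a2)
    if np.isscalar(rc_a1) or np.ndim(rc_a1) == 0:
        return int(a1), int(a2)
    return a1, a2


def allelic_ratio(rc_a1, rc_a2):
    """RC_A1 / (RC_A1 + RC_A2); NaN when the total is zero.

    The one-read rule is *not* applied here; the pipeline applies it first.
    """
    a1 = np.asarray(rc_a1, dtype=float)
    a2 = np.asarray(rc_a2, dtype=float)
    total = a1 + a2
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(total > 0, a1 / np.where(total > 0, total, 1), np.nan)
    if np.isscalar(rc_a1) or np.ndim(rc_a1) == 0:
        return float(ratio)
    return ratio


def _effective_ratio(rc_a1, rc_a2):
    a1, a2 = one_read_rule(rc_a1, rc_a2)
    return allelic_ratio(a1, a2)


def diploid_call(rc_a1, rc_a2):
    """Diploid genotype code from raw allele counts.

    Applies the one-read rule internally, then the 0.1/0.9 thresholds
    (boundaries homozygous).  Vectorized over arrays.
    """
    ratio = _effective_ratio(rc_a1, rc_a2)
    scalar = np.ndim(ratio) == 0
    r = np.atleast_1d(ratio)
    out = np.full(r.shape, MISSING, dtype=np.int8)
    valid = ~np.isnan(r)
    out[valid & (r <= HET_LOW)] = HOM_A2
    out[valid & (r >= HET_HIGH)] = HOM_A1
    out[valid & (r > HET_LOW) & (r < HET_HIGH)] = HET
    if scalar:
        return int(out[0])
    return out


def tetraploid_call(rc_a1, rc_a2):
    """Tetraploid A1 dosage code (0..4, or -1 missing) from raw counts.

    The homozygous classes 4|0 and 0|4 occupy exactly the diploid homozygote
    regions (ratio >= 0.9 resp. <= 0.1), keeping the two calling modes
    consistent.  Inside the heterozygous interval the dosage is the nearest
    quarter, with midpoints (ratio 0.375 and 0.625) resolved toward the
    balanced 2|2 class - conservative against dosage overcall at the edges.
    """
    ratio = _effective_ratio(rc_a1, rc_a2)
    scalar = np.ndim(ratio) == 0
    r = np.atleast_1d(ratio)
    out = np.full(r.shape, TETRA_MISSING, dtype=np.int8)
    valid = ~np.isnan(r)
    out[valid & (r <= HET_LOW)] = 0
    out[valid & (r >= HET_HIGH)] = 4
    het = valid & (r > HET_LOW) & (r < HET_HIGH)
    # nearest of {1,2,3} to 4r; ties (4r = 1.5 or 2.5) go to 2
    out[het & (r < 0.375)] = 1
    out[het & (r >= 0.375) & (r <= 0.625)] = 2
    out[het & (r > 0.625)] = 3
    if scalar:
        return int(out[0])
    return out


def call_genotype(rc_a1: int, rc_a2: int) -> GenotypeCall:
    """Full scalar call (diploid + tetraploid + effective ratio)."""
    return GenotypeCall(
        diploid=diploid_call(rc_a1, rc_a2),
        tetraploid=tetraploid_call(rc_a1, rc_a2),
        ratio=_effective_ratio(rc_a1, rc_a2),
    )


def call_matrix(rc1, rc2, mode: str = "diploid"):
    """Call every cell of a pair of loci x samples count matrices.

    Parameters
    ----------
    rc1, rc2 : pandas.DataFrame or ndarray
        Per-allele read counts, identically indexed.
    mode : "diploid" | "tetraploid"

    Returns an object of the same type holding int8 call codes.
    """
    import pandas as pd

    a1 = np.asarray(rc1)
    a2 = np.asarray(rc2)
    if a1.shape != a2.shape:
        raise ValueError("allele count matrices must have identical shape")
    fn = {"diploid": diploid_call, "tetraploid": tetraploid_call}.get(mode)
    if fn is None:
        raise ValueError(f"unknown mode {mode!r}")
    codes = fn(a1, a2)
    if isinstance(rc1, pd.DataFrame):
        return pd.DataFrame(codes, index=rc1.index, columns=rc1.columns)
    return codes
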