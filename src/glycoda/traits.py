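"""Derived N-glycan traits from the 46 HILIC-UPLC glycan peaks.

Peaks sharing a structural feature are summed into 17 derived traits:
galactosylation G0-G4 (number of galactoses), sialylation S0-S4 (number
of sialic acids), branching/antennarity A1-A4, core fucosylation CF,
outer-arm fucosylation OF, and oligomannose OM.  A handful of peaks
contain co-eluting structures and contribute fractionally (1/2 or 1/3)
to two traits; weights are kept as exact fractions so that identities
such as G3 == A3 hold bit-for-bit.

Three weight families partition the total abundance:

* S0+S1+S2+S3+S4 = 100 (every peak has sialylation weight exactly 1),
* G0+..+G4+OM = 100,
* A1+..+A4+OM = 100,

whereas CF and OF are plain bounded traits (subsets of peaks), not
partitions.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pandas as pd

from .coda import GP_COLUMNS, N_PEAKS

__all__ = [
    "TRAIT_NAMES",
    "trait_weights",
    "weight_matrix",
    "derive_traits",
    "trait_table",
    "export_weights_tsv",
]

TRAIT_NAMES = [
    "G0", "G1", "G2", "G3", "G4",
    "S0", "S1", "S2", "S3", "S4",
    "A1", "A2", "A3", "A4",
    "CF", "OF", "OM",
]

H = Fraction(1, 2)
T = Fraction(1, 3)


def _w(*items):
    """items: ints (weight 1) or (peak, weight) pairs -> list of pairs."""
    out = []
    for it in items:
        if isinstance(it, tuple):
            out.append((it[0], it[1]))
        else:
            out.append((it, Fraction(1)))
    return out


def _r(a, b):
    """Inclusive peak range a..b."""
    return list(range(a, b + 1))


_TRAIT_WEIGHTS = {
    # Galactosylation: number of galactose residues
    "G0": _w(1, 2, 4, 5, (6, H), (12, H)),
    "G1": _w(3, *_r(7, 10), (12, H), *_r(16, 18), (21, H)),
    "G2": _w(*_r(13, 15), 19, 20, (21, H), *_r(22, 28)),
    "G3": _w(29, *_r(31, 37)),
    "G4": _w(30, *_r(38, 46)),
    # Sialylation: number of sialic acids
    "S0": _w(*_r(1, 15)),
    "S1": _w(*_r(16, 23), 30),
    "S2": _w(*_r(24, 29), 31),
    "S3": _w(*_r(32, 40)),
    "S4": _w(*_r(41, 46)),
    # Branching (antennarity)
    "A1": _w(*_r(1, 3), (12, H), (21, H)),
    "A2": _w(4, 5, (6, H), *_r(7, 10), (12, H), *_r(13, 20), (21, H), *_r(22, 28)),
    "A3": _w(29, *_r(31, 37)),
    "A4": _w(30, *_r(38, 46)),
    # Fucosylation
    "CF": _w(2, 5, (6, H), *_r(8, 10), 14, 15, 17, 18, 22, 23, 27, 28, 36, (44, H)),
    "OF": _w(37, 40, (41, T), 45, (46, T)),
    # Oligomannose
    "OM": _w((6, H), 11),
}


def trait_weights() -> dict[str, list[tuple[int, Fraction]]]:
    """The constant trait weight map: trait -> [(peak number, weight), ...].

    Weights are exact :class:`fractions.Fraction` values in {1, 1/2, 1/3}.
    """
    return {t: list(pairs) for t, pairs in _TRAIT_WEIGHTS.items()}


def weight_matrix(dtype=float) -> np.ndarray:
    """Dense 17 x 46 weight matrix W, ordered as TRAIT_NAMES x GP1..GP46."""
    w = np.zeros((len(TRAIT_NAMES), N_PEAKS), dtype=dtype)
    for i, t in enumerate(TRAIT_NAMES):
        for peak, wt in _TRAIT_WEIGHTS[t]:
            w[i, peak - 1] += float(wt)
    return w


def derive_traits(composition) -> pd.Series:
    """Trait profile of one closed composition (46 percent values).

    Returns a Series indexed by TRAIT_NAMES, in percent of total area.
    """
    x = np.asarray(composition, dtype=float)
    if x.shape != (N_PEAKS,):
        raise ValueError(f"expected a {N_PEAKS}-part composition")
    return pd.Series(weight_matrix() @ x, index=TRAIT_NAMES)


def trait_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Row-wise derived traits for a cohort table with GP1..GP46 columns."""
    missing = [c for c in GP_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"missing glycan peak column(s): {', '.join(missing)}")
    gp = cohort[GP_COLUMNS].to_numpy(dtype=float)
    vals = gp @ weight_matrix().T
    return pd.DataFrame(vals, index=cohort.index, columns=TRAIT_NAMES)


def export_weights_tsv(path) -> None:
    """Write the weight map as a (trait, peak, weight) TSV for audit."""
    rows = [
        {"trait": t, "peak": f"GP{p}", "weight": str(wt)}
        for t, pairs in _TRAIT_WEIGHTS.items()
        for p, wt in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
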