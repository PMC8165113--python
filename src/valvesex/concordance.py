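"""Matched-pair 2x2 concordance scores and extreme-quadrant gene selection.

For every gene, a *sex score* is the fraction of matched male-female
comparisons (same tissue grade) in which the male value is higher, and a
*tissue score* is the fraction of patients whose calcified sample exceeds
their nondiseased sample. Ties contribute 0.5, which preserves exact
antisymmetry under a sex-label swap. Both scores live in [0, 1] with 0.5 as
the no-difference centre; genes far from (0.5, 0.5) in a quadrant are the
"extremes" of that quadrant.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, TISSUE_LEVELS
from .matching import MatchResult

QUADRANT_NAMES = (
    "male_calcified",
    "male_nondiseased",
    "female_calcified",
    "female_nondiseased",
)


@dataclass
class ConcordanceScores:
    """Per-gene (sex_score, tissue_score) pairs plus comparison counts.

    ``frame`` also carries ``sex_wins``/``tissue_wins``, the raw
    half-integer win counts (exact, unlike the score means which incur one
    float division).
    """

    frame: pd.DataFrame  # columns: sex_score, tissue_score, sex_wins, tissue_wins
    n_pairs: int
    n_patients: int
    n_sex_comparisons: int = 0

    @property
    def sex_score(self) -> pd.Series:
        return self.frame["sex_score"]

    @property
    def tissue_score(self) -> pd.Series:
        return self.frame["tissue_score"]


@dataclass
class QuadrantSets:
    """The four extreme-gene lists; keys name the (sex, tissue) direction."""

    sets: dict
    fraction: float

    def __getitem__(self, name: str) -> list:
        return self.sets[name]

    def all_genes(self) -> list:
        return [g for name in QUADRANT_NAMES for g in self.sets[name]]


def score_genes(
    expr: ExpressionMatrix,
    pairs: MatchResult,
    tissues=TISSUE_LEVELS,
) -> ConcordanceScores:
    """Compute the per-gene sex and tissue concordance scores.

    Sex comparisons use same-grade samples of the two patients in each
    matched pair, across all requested grades. Tissue comparisons use each
    matched patient's calcified vs nondiseased samples. A comparison whose
    samples are missing is dropped with a warning.
    """
    if not pairs.pairs:
        raise ValueError("empty pair set")
    lookup = expr.sample_lookup()
    values = expr.values

    male_cols, female_cols = [], []
    for m, f in pairs.pairs:
        for tissue in tissues:
            sm_, sf = lookup.get((m, tissue)), lookup.get((f, tissue))
            if sm_ is None or sf is None:
                warnings.warn(f"pair ({m}, {f}) lacks a {tissue} sample; comparison skipped")
                continue
            male_cols.append(sm_)
            female_cols.append(sf)
    if not male_cols:
        raise ValueError("no usable sex comparisons")

    xm = values[male_cols].to_numpy()
    xf = values[female_cols].to_numpy()
    # half-integer win counts are exact in binary floats; the derived mean
    # is the only rounded quantity
    sex_wins = ((xm > xf) + 0.5 * (xm == xf)).sum(axis=1)
    sex_score = sex_wins / len(male_cols)

    cal_cols, non_cols, used_patients = [], [], []
    for patient in dict.fromkeys(pairs.matched_patients()):
        sc, sn = lookup.get((patient, "calcified")), lookup.get((patient, "nondiseased"))
        if sc is None or sn is None:
            warnings.warn(f"patient {patient} lacks calcified or nondiseased sample; excluded")
            continue
        cal_cols.append(sc)
        non_cols.append(sn)
        used_patients.append(patient)
    if not cal_cols:
        raise ValueError("no patient has both calcified and nondiseased samples")

    xc = values[cal_cols].to_numpy()
    xn = values[non_cols].to_numpy()
    tissue_wins = ((xc > xn) + 0.5 * (xc == xn)).sum(axis=1)
    tissue_score = tissue_wins / len(cal_cols)

    frame = pd.DataFrame(
        {
            "sex_score": sex_score,
            "tissue_score": tissue_score,
            "sex_wins": sex_wins,
            "tissue_wins": tissue_wins,
        },
        index=values.index,
    )
    scores = ConcordanceScores(
        frame=frame, n_pairs=len(pairs.pairs), n_patients=len(used_patients)
    )
    scores.n_sex_comparisons = len(male_cols)
    return scores


def quadrant_extremes(
    scores: ConcordanceScores, fraction: float = 0.25, metric: str = "radial"
) -> QuadrantSets:
    """Select the extreme ``fraction`` of genes in each quadrant.

    Genes sitting exactly on an 0.5 axis belong to no quadrant. Within a
    quadrant genes are ranked by distance from the (0.5, 0.5) centre —
    Euclidean for ``metric="radial"``, Chebyshev-like per-axis minimum for
    ``metric="axis"`` — and the top ``ceil(fraction * quadrant_size)`` are
    kept, ties at the cutoff broken by gene id order.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    if metric not in ("radial", "axis"):
        raise ValueError(f"unknown extreme metric {metric!r}")
    dx = scores.sex_score - 0.5
    dy = scores.tissue_score - 0.5
    if metric == "radial":
        dist = np.hypot(dx, dy)
    else:
        dist = np.minimum(dx.abs(), dy.abs())

    sets = {}
    for name, (sx, sy) in {
        "male_calcified": (1, 1),
        "male_nondiseased": (1, -1),
        "female_calcified": (-1, 1),
        "female_nondiseased": (-1, -1),
    }.items():
        mask = (np.sign(dx) == sx) & (np.sign(dy) == sy)
        genes = scores.frame.index[mask]
        if len(genes) == 0 or fraction == 0.0:
            sets[name] = []
            continue
        n_keep = math.ceil(fraction * len(genes))
        order = sorted(genes, key=lambda g: (-dist[g], g))
        sets[name] = order[:n_keep]
    return QuadrantSets(sets=sets, fraction=fraction)
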