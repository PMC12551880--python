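"""Variation partitioning of community dissimilarity over predictor sets.

The adjusted R^2 of a dbRDA is computed for every non-empty union of the
predictor sets (2^k - 1 models; 31 for the five sets spatial, temporal,
structural, environmental, anthropogenic).  Exclusive fractions for every
non-empty combination of sets are then obtained by inclusion-exclusion
over those union values, so the 2^k - 1 fractions plus the residual
1 - adjR^2(all sets) sum to 1 by construction.  Fractions can be
negative; a negative interaction fraction means the overlap interferes
with, rather than adds to, the variation the other sets explain, and is
reported as-is.

Per-set significance conditional on the remaining sets uses a partial
dbRDA pseudo-F with Freedman-Lane residual permutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import chain, combinations

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from wcscomm.ordination import PcoOrdination, dbrda, pco

__all__ = ["PartitionResult", "partition", "set_significance"]


@dataclass
class PartitionResult:
    """Exclusive variation fractions over predictor sets.

    ``fractions`` maps each non-empty combination of set labels (a tuple
    in the declared set order) to its exclusive fraction; ``adj_r2`` maps
    each non-empty union to the adjusted R^2 of its dbRDA.
    """

    set_labels: list[str]
    fractions: dict[tuple[str, ...], float]
    residual: float
    adj_r2: dict[tuple[str, ...], float]
    set_tests: pd.DataFrame | None = field(default=None, repr=False)

    def unique_fraction(self, label: str) -> float:
        return self.fractions[(label,)]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subset": "+".join(k), "n_sets": len(k), "fraction": v}
            for k, v in self.fractions.items()
        ]
        rows.append({"subset": "<residual>", "n_sets": 0, "fraction": self.residual})
        return pd.DataFrame(rows)

    def total_explained(self) -> float:
        return sum(self.fractions.values())


def _nonempty_subsets(labels: list[str]):
    return chain.from_iterable(
        combinations(labels, r) for r in range(1, len(labels) + 1)
    )


def partition(
    dissim: DistanceMatrix | PcoOrdination,
    predictors: pd.DataFrame,
    sets: dict[str, list[str]],
    n_perm: int = 0,
    seed: int | np.random.Generator | None = None,
) -> PartitionResult:
    """Partition explained variation among predictor sets.

    Parameters
    ----------
    dissim : DistanceMatrix or PcoOrdination
        Community dissimilarity response.
    predictors : DataFrame
        Observations x predictor columns (numeric; categoricals already
        dummy-coded).
    sets : dict
        Mapping set label -> list of predictor column names.  Every set
        must be non-empty and the full design non-singular.
    n_perm : int
        When positive, run the conditional per-set permutation tests and
        attach them as ``set_tests``.
    """
    labels = list(sets)
    for lab, cols in sets.items():
        if not cols:
            raise ValueError(f"predictor set {lab!r} is empty")
        missing = [c for c in cols if c not in predictors.columns]
        if missing:
            raise KeyError(f"set {lab!r} references missing columns {missing}")

    ordination = dissim if isinstance(dissim, PcoOrdination) else pco(dissim)

    adj_r2: dict[tuple[str, ...], float] = {}
    for union in _nonempty_subsets(labels):
        cols = [c for lab in union for c in sets[lab]]
        # rank-tolerant: aliased columns drop out of the projection and the
        # Ezekiel penalty uses the union's rank, as constrained-ordination
        # software does
        fit = dbrda(ordination, predictors[cols], n_perm=0, strict=False)
        adj_r2[union] = fit.adj_r2

    def r(subset: tuple[str, ...]) -> float:
        if not subset:
            return 0.0
        return adj_r2[tuple(l for l in labels if l in subset)]

    # inclusion-exclusion: intersection measures from union measures,
    # then exclusive regions by Moebius inversion over supersets
    inter: dict[tuple[str, ...], float] = {}
    for w in _nonempty_subsets(labels):
        total = 0.0
        for t in _nonempty_subsets(list(w)):
            total += (-1) ** (len(t) + 1) * r(t)
        inter[w] = total

    fractions: dict[tuple[str, ...], float] = {}
    for s in _nonempty_subsets(labels):
        sset = set(s)
        val = 0.0
        for w in _nonempty_subsets(labels):
            if sset <= set(w):
                val += (-1) ** (len(w) - len(s)) * inter[w]
        fractions[s] = val

    residual = 1.0 - r(tuple(labels))

    set_tests = None
    if n_perm:
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        rows = []
        for lab in labels:
            f, p = set_significance(
                ordination,
                predictors,
                target=sets[lab],
                conditioning=[c for l in labels if l != lab for c in sets[l]],
                n_perm=n_perm,
                seed=rng,
            )
            rows.append({"set": lab, "pseudo_F": f, "p_value": p})
        set_tests = pd.DataFrame(rows)

    return PartitionResult(
        set_labels=labels,
        fractions=fractions,
        residual=residual,
        adj_r2=adj_r2,
        set_tests=set_tests,
    )


def set_significance(
    dissim: DistanceMatrix | PcoOrdination,
    predictors: pd.DataFrame,
    target: list[str],
    conditioning: list[str],
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Partial pseudo-F and permutation p for a target predictor set.

    Tests the inertia explained by ``target`` given the ``conditioning``
    columns, with Freedman-Lane permutation of reduced-model residuals;
    p = (exceedances + 1) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("use at least 99 permutations")
    ordination = dissim if isinstance(dissim, PcoOrdination) else pco(dissim)
    overlap = [c for c in target if c in conditioning]
    if overlap:
        raise ValueError(
            f"target columns nested in conditioning set leave zero df: {overlap}"
        )
    fit = dbrda(
        ordination,
        predictors[target],
        condition=predictors[conditioning] if conditioning else None,
        n_perm=n_perm,
        seed=seed,
    )
    return fit.pseudo_f, fit.p_value
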