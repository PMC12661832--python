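"""Sample-level functional-content metrics.

Builds incidence matrices (reaction/pathway/EC presence per sample,
binary or abundance-weighted), Jaccard and Bray-Curtis dissimilarities,
principal coordinates (classical MDS), pairwise mutual information on
binary reaction content, the community metabolic dissimilarity (CMD)
score, and the metabolic resource overlap (MRO) between member species'
minimal nutrient requirements.
"""

from __future__ import annotations

import itertools
import logging
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from . import config
from .gem_core import GEM, ModelError, minimal_medium
from .synthetic_community import CommunitySample

logger = logging.getLogger(__name__)

__all__ = [
    "build_incidence",
    "dissimilarity",
    "pcoa",
    "mutual_information",
    "mi_pairs",
    "cmd_score",
    "mro_score",
]

_FEATURE_GETTERS = {
    "reaction": lambda gem: gem.reaction_id_set,
    "pathway": lambda gem: gem.pathway_set,
    "EC": lambda gem: gem.ec_set,
}


def build_incidence(
    samples: Sequence[CommunitySample],
    models: Mapping[str, GEM],
    mode: str = "binary",
    feature: str = "reaction",
) -> pd.DataFrame:
    """Samples x features incidence matrix.

    Binary mode marks a feature present when any member species carries
    it; weighted mode sums the relative abundances of the members carrying
    it (a feature shared by all members scores 1).
    """
    if mode not in {"binary", "weighted"}:
        raise ValueError(f"unknown mode {mode!r}")
    if feature not in _FEATURE_GETTERS:
        raise ValueError(f"unknown feature kind {feature!r}")
    getter = _FEATURE_GETTERS[feature]
    for s in samples:
        missing = sorted(set(s.members) - set(models))
        if missing:
            raise ModelError(f"sample {s.sample_id!r}: no model for {missing}")
    universe = sorted(set().union(*(getter(models[sp]) for s in samples for sp in s.members)))
    data = np.zeros((len(samples), len(universe)))
    col = {f: j for j, f in enumerate(universe)}
    for i, s in enumerate(samples):
        for sp, ab in s.members.items():
            w = 1.0 if mode == "binary" else ab
            for f in getter(models[sp]):
                if mode == "binary":
                    data[i, col[f]] = 1.0
                else:
                    data[i, col[f]] += w
    return pd.DataFrame(data, index=[s.sample_id for s in samples], columns=universe)


def dissimilarity(matrix: pd.DataFrame, metric: str = "jaccard") -> pd.DataFrame:
    """Sample x sample Jaccard or Bray-Curtis dissimilarity matrix."""
    if metric == "jaccard":
        values = matrix.to_numpy()
        if not np.isin(values, (0.0, 1.0)).all():
            raise ValueError("Jaccard requires a binary incidence matrix")
        d = pdist(values.astype(bool), metric="jaccard")
    elif metric == "bray_curtis":
        values = matrix.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValueError("Bray-Curtis requires nonnegative values")
        d = pdist(values, metric="braycurtis")
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return pd.DataFrame(squareform(d), index=matrix.index, columns=matrix.index)


def pcoa(distances: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Classical scaling (principal coordinate analysis).

    Double-centers the squared distance matrix, eigendecomposes the Gram
    matrix and returns coordinates on the positive-eigenvalue axes plus
    the percent variance explained by each axis (eigenvalue over the sum
    of positive eigenvalues). Negative eigenvalues from non-Euclidean
    input are dropped.
    """
    D = distances.to_numpy(dtype=float)
    if D.shape[0] != D.shape[1] or not np.allclose(D, D.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals).max(initial=0.0))
    if not pos.any():
        coords = pd.DataFrame(
            np.zeros((n, 1)), index=distances.index, columns=["PC1"]
        )
        return coords, np.array([0.0])
    lam = eigvals[pos]
    coords = eigvecs[:, pos] * np.sqrt(lam)
    pct = 100.0 * lam / lam.sum()
    cols = [f"PC{i + 1}" for i in range(coords.shape[1])]
    return pd.DataFrame(coords, index=distances.index, columns=cols), pct


def mutual_information(x: Iterable[int], y: Iterable[int]) -> float:
    """Plug-in mutual information (nats) of two binary feature vectors.

    The R features are treated as R paired observations of (x, y) in
    {0,1}^2; MI = sum p(x,y) ln[p(x,y)/(p(x)p(y))] with 0*ln(0) = 0.
    """
    x = np.asarray(list(x), dtype=int)
    y = np.asarray(list(y), dtype=int)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("need two equal-length non-empty binary vectors")
    n = x.size
    mi = 0.0
    for xv in (0, 1):
        px = np.mean(x == xv)
        for yv in (0, 1):
            pxy = np.mean((x == xv) & (y == yv))
            py = np.mean(y == yv)
            if pxy > 0:
                mi += pxy * math.log(pxy / (px * py))
    return max(mi, 0.0)


def mi_pairs(incidence: pd.DataFrame) -> pd.DataFrame:
    """Pairwise MI between all sample rows of a binary incidence matrix."""
    rows = []
    ids = list(incidence.index)
    for i, j in itertools.combinations(range(len(ids)), 2):
        mi = mutual_information(incidence.iloc[i], incidence.iloc[j])
        rows.append({"sample_i": ids[i], "sample_j": ids[j], "mi": mi})
    return pd.DataFrame(rows, columns=["sample_i", "sample_j", "mi"])


def cmd_score(ec_sets: Mapping[str, frozenset[str] | set[str]]) -> tuple[float, float]:
    """Community metabolic dissimilarity of one sample's member species.

    Returns ``(cmd, mean_distance)`` where ``mean_distance`` is the mean
    off-diagonal pairwise Jaccard distance between member EC sets and
    ``cmd = mean_distance * log2(S)`` — the logarithmic size adjustment
    rewards additional species with diminishing returns. The unadjusted
    mean is returned alongside so other adjustments can be applied.
    """
    species = sorted(ec_sets)
    s_count = len(species)
    if s_count < 2:
        raise ValueError(f"need at least 2 species, got {s_count}")
    dists = []
    for a, b in itertools.combinations(species, 2):
        sa, sb = set(ec_sets[a]), set(ec_sets[b])
        union = sa | sb
        dists.append(1.0 - (len(sa & sb) / len(union)) if union else 0.0)
    mean_dist = float(np.mean(dists))
    return mean_dist * math.log2(s_count), mean_dist


def mro_score(
    models: Mapping[str, GEM],
    candidate_nutrients: Iterable[str],
    growth_threshold: float = config.GROWTH_THRESHOLD,
) -> tuple[float, dict[str, frozenset[str]]]:
    """Metabolic resource overlap of a community.

    Computes each member's minimal nutrient requirement on the candidate
    medium and averages, over unordered member pairs, the overlap
    |Mi ∩ Mj| / min(|Mi|, |Mj|). Higher values mean more potential
    competition for the same resources. A member that fails to grow on
    the full candidate medium raises an error naming the species.
    """
    candidates = sorted(set(candidate_nutrients))
    media: dict[str, frozenset[str]] = {}
    for sp in sorted(models):
        try:
            media[sp] = minimal_medium(models[sp], candidates, growth_threshold)
        except ModelError as exc:
            raise ModelError(f"species {sp!r} cannot grow on the medium") from exc
    species = sorted(media)
    if len(species) < 2:
        raise ValueError(f"need at least 2 members, got {len(species)}")
    overlaps = []
    for a, b in itertools.combinations(species, 2):
        ma, mb = media[a], media[b]
        smallest = min(len(ma), len(mb))
        # A species with an empty requirement set competes for nothing.
        overlaps.append(len(ma & mb) / smallest if smallest else 0.0)
    return float(np.mean(overlaps)), media
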