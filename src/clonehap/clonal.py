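"""Clonal-structure estimation from variant allele frequencies.

Under linear evolution with clone proportions ``r_0..r_{I-1}`` (founding
clone first), a heterozygous site arising in clone ``s`` is carried by
every descendant, so its expected VAF is ``0.5 * sum_{i>=s} r_i``.  VAFs
therefore fall into ``I`` clusters with strictly decreasing means, one per
clone, and the cluster means invert to the proportions in closed form:

    r_i = 2 * (mean_i - mean_{i+1}),   with mean_I := 0.

Clustering is a 1-D Gaussian mixture; the number of components is chosen
by BIC unless fixed by the caller.  Clusters whose means are closer than a
minimum separation (default 0.05, roughly the binomial VAF noise at 100x
depth) are merged before labelling, which keeps BIC from splitting a
single clone's binomial scatter in two.  Sites with VAF near 1 would be
homozygous founding-clone mutations; they are uninformative for phasing
and are flagged for exclusion.  An import hook accepts externally computed
site-to-cluster tables.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .vpe import SiteSet

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ClonalStructure:
    """Inferred clonal architecture.

    Clone labels are ordered by decreasing cluster mean VAF, so label 0 is
    the founding clone.  ``assignments[j]`` is the clone of site ``j`` (-1
    where the VAF was undefined); ``homozygous`` flags sites excluded from
    phasing as apparent homozygous founding mutations.
    """

    n_subclones: int
    assignments: np.ndarray
    cluster_means: np.ndarray
    proportions: np.ndarray
    homozygous: np.ndarray

    def __post_init__(self):
        if np.any(np.diff(self.cluster_means) >= 0):
            raise ValueError("cluster means must be strictly decreasing")

    @property
    def founding_sites(self) -> np.ndarray:
        """Indices of phaseable founding-clone sites."""
        return np.flatnonzero((self.assignments == 0) & ~self.homozygous)

    @property
    def phaseable(self) -> np.ndarray:
        return np.flatnonzero((self.assignments >= 0) & ~self.homozygous)


def estimate_proportions(cluster_means, tol: float = 0.1) -> np.ndarray:
    """Invert cluster mean VAFs to clone proportions.

    Uses ``mean_i = 0.5 * sum_{k>=i} r_k``, i.e. ``r_i = 2 * (mean_i -
    mean_{i+1})`` with ``mean_I = 0``; negative components (possible under
    noise) are clamped to zero and the vector renormalized.
    """
    means = np.asarray(cluster_means, dtype=float)
    if len(means) == 0:
        raise ValueError("no cluster means")
    if np.any(np.diff(means) >= 0):
        raise ValueError("cluster means must be strictly decreasing")
    if means[0] > 0.5 + tol:
        raise ValueError(
            f"largest cluster mean {means[0]:.3f} exceeds the heterozygous "
            f"ceiling 0.5 + {tol}"
        )
    ext = np.append(means, 0.0)
    r = 2.0 * np.diff(ext) * -1.0
    r = np.clip(r, 0.0, None)
    total = r.sum()
    if total <= 0:
        raise ValueError("degenerate cluster means")
    return r / total


def cluster_vafs(
    vafs,
    max_clusters: int = 6,
    fixed_subclones: int | None = None,
    seed: int = 0,
    min_separation: float = 0.05,
    hom_threshold: float = 0.9,
) -> ClonalStructure:
    """Cluster per-site VAFs into sub-clones.

    Parameters
    ----------
    vafs
        Per-site VAF array (nan = undefined, excluded).
    max_clusters
        Upper bound for BIC model selection.
    fixed_subclones
        Skip model selection and fit exactly this many components.
    min_separation
        Clusters with means closer than this are merged (ignored when the
        count is fixed by ``fixed_subclones``).
    hom_threshold
        Sites with VAF above this are flagged homozygous-founding and
        excluded from clustering and phasing.
    """
    vafs = np.asarray(vafs, dtype=float)
    valid = np.isfinite(vafs)
    homozygous = valid & (vafs > hom_threshold)
    use = valid & ~homozygous
    x = vafs[use]
    n_target = fixed_subclones if fixed_subclones is not None else max_clusters
    if n_target < 1:
        raise ValueError("cluster count must be >= 1")
    if len(x) < n_target:
        raise ValueError(
            f"only {len(x)} sites with defined VAF; need >= {n_target}"
        )
    if np.ptp(x) < 1e-9:
        labels = np.zeros(len(x), dtype=np.int64)
        means = np.array([float(x[0])])
        weights = np.array([1.0])
    else:
        X = x[:, None]
        if fixed_subclones is not None:
            gmm = _fit(X, fixed_subclones, seed)
        else:
            best, best_bic = None, np.inf
            for k in range(1, max_clusters + 1):
                cand = _fit(X, k, seed)
                bic = cand.bic(X)
                if bic < best_bic - 1e-9:
                    best, best_bic = cand, bic
            gmm = best
        labels = gmm.predict(X)
        means = gmm.means_.ravel()
        weights = gmm.weights_.ravel()
        if fixed_subclones is None and min_separation > 0:
            labels, means, weights = _merge_close(
                labels, means, weights, min_separation
            )
    # relabel by decreasing mean: clone 0 = founding (highest VAF)
    order = np.argsort(-means, kind="stable")
    relabel = np.empty(len(means), dtype=np.int64)
    relabel[order] = np.arange(len(means))
    means_sorted = means[order]
    assignments = np.full(len(vafs), -1, dtype=np.int64)
    assignments[use] = relabel[labels]
    assignments[homozygous] = 0  # VAF ~ 1 implies the founding clone
    proportions = estimate_proportions(np.minimum(means_sorted, 0.5 + 0.099))
    return ClonalStructure(
        n_subclones=len(means_sorted),
        assignments=assignments,
        cluster_means=means_sorted,
        proportions=proportions,
        homozygous=homozygous,
    )


def _fit(X, k, seed):
    return GaussianMixture(
        n_components=k,
        covariance_type="full",
        n_init=3,
        random_state=seed,
        reg_covar=1e-6,
    ).fit(X)


def _merge_close(labels, means, weights, min_separation):
    """Merge mixture components whose means are closer than the floor."""
    comps = [(float(m), float(w), [k]) for k, (m, w) in enumerate(zip(means, weights))]
    comps.sort(key=lambda c: c[0])
    changed = True
    while changed and len(comps) > 1:
        changed = False
        for i in range(len(comps) - 1):
            m0, w0, ids0 = comps[i]
            m1, w1, ids1 = comps[i + 1]
            if m1 - m0 < min_separation:
                w = w0 + w1
                comps[i] = ((m0 * w0 + m1 * w1) / w, w, ids0 + ids1)
                del comps[i + 1]
                changed = True
                break
    remap = np.empty(len(means), dtype=np.int64)
    for new_id, (_, _, ids) in enumerate(comps):
        for old in ids:
            remap[old] = new_id
    new_means = np.array([c[0] for c in comps])
    new_weights = np.array([c[1] for c in comps])
    return remap[labels], new_means, new_weights


def import_clusters(table, sites: SiteSet) -> ClonalStructure:
    """Adopt an externally computed site-to-cluster table.

    ``table`` is a DataFrame (or path to a TSV) with columns ``position``
    and ``cluster``; cluster ids are arbitrary and are relabelled by
    decreasing mean VAF.  Positions absent from ``sites`` are skipped with
    a warning; if nothing matches, that is an error.  Proportions are
    re-derived from the cluster means.
    """
    if not isinstance(table, pd.DataFrame):
        table = pd.read_csv(table, sep="\t")
    if not {"position", "cluster"} <= set(table.columns):
        raise ValueError("cluster table needs 'position' and 'cluster' columns")
    if sites.vaf is None:
        raise ValueError("sites must carry VAFs before importing clusters")
    pos_to_idx = {int(p): j for j, p in enumerate(sites.positions)}
    assignments_raw = np.full(len(sites), -1, dtype=np.int64)
    skipped = 0
    for pos, cl in zip(table["position"], table["cluster"]):
        j = pos_to_idx.get(int(pos))
        if j is None:
            skipped += 1
            continue
        assignments_raw[j] = int(cl)
    if skipped:
        logger.warning("import_clusters: %d positions not in site list", skipped)
    if np.all(assignments_raw < 0):
        raise ValueError("no imported position matches the site list")
    ids = np.unique(assignments_raw[assignments_raw >= 0])
    means = np.array(
        [np.nanmean(sites.vaf[assignments_raw == c]) for c in ids]
    )
    order = np.argsort(-means, kind="stable")
    relabel = {int(ids[o]): rank for rank, o in enumerate(order)}
    assignments = np.array(
        [relabel[int(c)] if c >= 0 else -1 for c in assignments_raw],
        dtype=np.int64,
    )
    means_sorted = means[order]
    homozygous = np.isfinite(sites.vaf) & (sites.vaf > 0.9)
    proportions = estimate_proportions(np.minimum(means_sorted, 0.599))
    return ClonalStructure(
        n_subclones=len(ids),
        assignments=assignments,
        cluster_means=means_sorted,
        proportions=proportions,
        homozygous=homozygous,
    )
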