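"""Microstate template clustering.

Implements the atomize-and-agglomerate hierarchical clustering (AAHC) of
GFP-peak topographies, polarity-free throughout: maps are compared by
absolute spatial (Pearson) correlation, cluster templates are the dominant
eigenvector of the members' outer-product sum (a sign-free principal
component), and cluster quality is the global explained variance (GEV) --
the GFP-weighted squared correlation between each map and its template,
normalized by total squared GFP.

AAHC starts from singleton clusters and repeatedly dissolves the cluster
contributing least GEV, reassigning each orphaned map to the surviving
cluster of highest squared correlation, until k clusters remain.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from itertools import permutations

import numpy as np

from .datatypes import (
    InvalidInputError,
    TemplateSet,
    UndefinedResultError,
    default_state_names,
)


def spatial_correlation(u: np.ndarray, v: np.ndarray) -> float:
    """Absolute Pearson correlation between two topographies (polarity-free).

    Both maps are re-referenced (mean removed) before correlating.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InvalidInputError("topographies must share the channel count")
    u = u - u.mean()
    v = v - v.mean()
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise UndefinedResultError("correlation undefined for a flat map")
    return float(abs(u @ v) / (nu * nv))


def _normalize_maps(maps: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Zero-mean, unit-norm rows plus the original row norms (the GFP up to
    the 1/sqrt(C) factor, which cancels in GEV ratios)."""
    maps = np.asarray(maps, dtype=float)
    maps = maps - maps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(maps, axis=1)
    if np.any(norms == 0):
        raise InvalidInputError("flat (zero-variance) map in input")
    return maps / norms[:, None], norms


def _dominant_eigenvector(scatter: np.ndarray) -> np.ndarray:
    """Unit eigenvector of the largest eigenvalue of a symmetric matrix."""
    vals, vecs = np.linalg.eigh(scatter)
    v = vecs[:, -1]
    v = v - v.mean()  # members are zero-mean, so this is a no-op up to float fuzz
    return v / np.linalg.norm(v)


@dataclass
class ClusterSolution:
    """AAHC output: templates, per-map assignment, and the achieved GEV."""

    templates: TemplateSet
    assignment: np.ndarray
    gev: float


def gev(maps: np.ndarray, gfp_at_peaks: np.ndarray, templates: TemplateSet,
        assignment: np.ndarray) -> float:
    """Global explained variance of an assignment.

    GEV = sum_t (GFP_t * corr(map_t, template_a(t)))^2 / sum_t GFP_t^2.
    """
    gfp_at_peaks = np.asarray(gfp_at_peaks, dtype=float)
    denom = float(np.sum(gfp_at_peaks ** 2))
    if denom == 0:
        raise UndefinedResultError("GEV undefined when all GFP values are 0")
    normed, _ = _normalize_maps(maps)
    corr = np.abs(np.einsum("tc,tc->t", normed,
                            templates.maps[np.asarray(assignment)]))
    return float(np.sum((gfp_at_peaks * corr) ** 2) / denom)


def aahc(maps: np.ndarray, gfp_at_peaks: np.ndarray, k: int = 4,
         channel_labels: list[str] | None = None) -> ClusterSolution:
    """Atomize-and-agglomerate clustering of peak maps into k templates.

    Deterministic for a fixed input order.  Ties in reassignment go to the
    lowest surviving cluster index.
    """
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    if n <= k:
        raise InvalidInputError(f"need more than k={k} maps, got {n}")
    normed, _ = _normalize_maps(maps)
    g = np.asarray(gfp_at_peaks, dtype=float)
    if g.shape != (n,):
        raise InvalidInputError("gfp_at_peaks must match the number of maps")

    members: list[list[int] | None] = [[i] for i in range(n)]
    templates = normed.copy()             # row per cluster
    scatters = np.einsum("tc,td->tcd", normed, normed)  # running outer sums
    # GEV contribution of a singleton is gfp^2 (corr with itself is 1)
    contrib = g.astype(float) ** 2
    alive = np.ones(n, dtype=bool)
    n_alive = n

    def refresh(c: int) -> None:
        idx = members[c]
        templates[c] = _dominant_eigenvector(scatters[c])
        proj = normed[idx] @ templates[c]
        contrib[c] = float(np.sum((g[idx] * proj) ** 2))

    while n_alive > k:
        alive_idx = np.flatnonzero(alive)
        worst = alive_idx[int(np.argmin(contrib[alive_idx]))]
        orphans = members[worst]
        alive[worst] = False
        members[worst] = None
        n_alive -= 1
        alive_idx = np.flatnonzero(alive)
        # squared correlation of each orphan map with every surviving template
        corr2 = (normed[orphans] @ templates[alive_idx].T) ** 2
        best = alive_idx[np.argmax(corr2, axis=1)]
        touched = set()
        for m, c in zip(orphans, best):
            members[c].append(m)
            scatters[c] += np.outer(normed[m], normed[m])
            touched.add(int(c))
        for c in touched:
            refresh(c)

    alive_idx = np.flatnonzero(alive)
    final_maps = templates[alive_idx]
    assignment = np.empty(n, dtype=np.int64)
    for new, c in enumerate(alive_idx):
        assignment[members[c]] = new
    ts = TemplateSet(final_maps, labels=default_state_names(k),
                     channel_labels=channel_labels or [])
    return ClusterSolution(ts, assignment,
                           gev(maps, g, ts, assignment))


def group_templates(individual: list[TemplateSet], max_iter: int = 100
                    ) -> TemplateSet:
    """Consensus templates across subjects by permutation alignment.

    Starting from the first subject's set as reference, each subject's maps
    are matched to the reference by the state permutation (exhaustive over
    K!) and per-map signs maximizing total spatial correlation; the reference
    is then recomputed as the sign-aligned mean, renormalized.  Iterates
    until the matching stabilizes.
    """
    if not individual:
        raise InvalidInputError("need at least one subject")
    k = individual[0].k
    c = individual[0].n_channels
    for ts in individual:
        if ts.k != k or ts.n_channels != c:
            raise InvalidInputError("all template sets must share K and C")
    if len(individual) == 1:
        return TemplateSet(individual[0].maps.copy(),
                           list(individual[0].labels),
                           list(individual[0].channel_labels))

    ref = individual[0].maps.copy()
    prev_perms: list[tuple[int, ...]] | None = None
    perms = list(permutations(range(k)))
    for _ in range(max_iter):
        aligned = np.zeros((len(individual), k, c))
        chosen: list[tuple[int, ...]] = []
        for s, ts in enumerate(individual):
            corr = ts.maps @ ref.T  # signed correlation, rows=subject maps
            best_perm, best_score = None, -np.inf
            for perm in perms:
                score = float(np.sum(np.abs(corr[list(perm), range(k)])))
                if score > best_score:
                    best_perm, best_score = perm, score
            chosen.append(best_perm)
            for j in range(k):
                m = ts.maps[best_perm[j]]
                aligned[s, j] = m if m @ ref[j] >= 0 else -m
        new_ref = aligned.mean(axis=0)
        norms = np.linalg.norm(new_ref, axis=1)
        if np.any(norms == 0):
            raise UndefinedResultError("degenerate consensus map")
        ref = new_ref / norms[:, None]
        if chosen == prev_perms:
            break
        prev_perms = chosen
    return TemplateSet(ref, labels=default_state_names(k),
                       channel_labels=list(individual[0].channel_labels))


def align_templates(ts: TemplateSet, reference: TemplateSet
                    ) -> tuple[TemplateSet, tuple[int, ...]]:
    """Reorder (and sign-align) ``ts`` to best match ``reference``.

    Exhaustive over the K! state permutations; returns the reordered set
    carrying the reference's labels, plus the permutation used (entry j is
    the row of ``ts`` assigned to reference state j).
    """
    if ts.k != reference.k:
        raise InvalidInputError("template sets must share K")
    k = ts.k
    corr = np.abs(ts.maps @ reference.maps.T)
    best_perm, best_score = None, -np.inf
    for perm in permutations(range(k)):
        score = float(np.sum(corr[list(perm), range(k)]))
        if score > best_score:
            best_perm, best_score = perm, score
    maps = ts.maps[list(best_perm)].copy()
    for j in range(k):
        if maps[j] @ reference.maps[j] < 0:
            maps[j] = -maps[j]
    return (TemplateSet(maps, labels=list(reference.labels),
                        channel_labels=list(ts.channel_labels)), best_perm)


def load_canonical_templates() -> TemplateSet:
    """Packaged canonical A-D archetypes on the default 31-channel montage.

    These fix label names only (via :func:`order_canonical`); they never
    enter any numeric result.
    """
    path = resources.files("msdyn.data") / "canonical_maps_k4.csv"
    with path.open() as fh:
        header = fh.readline().strip().split(",")
        maps = np.loadtxt(fh, delimiter=",")
    return TemplateSet(maps, labels=default_state_names(4),
                       channel_labels=header)


def order_canonical(ts: TemplateSet, canonical: TemplateSet | None = None
                    ) -> TemplateSet:
    """Relabel states A-D by best total correlation to the canonical maps."""
    if canonical is None:
        canonical = load_canonical_templates()
    if ts.k != canonical.k:
        raise InvalidInputError("K must match the canonical set")
    if ts.n_channels != canonical.n_channels:
        raise InvalidInputError("channel count must match the canonical set")
    ordered, _ = align_templates(ts, canonical)
    return TemplateSet(ordered.maps, labels=list(canonical.labels),
                       channel_labels=list(ts.channel_labels))
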