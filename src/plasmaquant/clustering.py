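"""Cross-run feature clustering on the (mass, calibrated rt) plane.

Every data point (one identified peptide record) seeds a candidate
cluster center.  Centers move iteratively to the mean of the points
inside their window — mass window +/- ``mass_window_ppm`` ppm of the
center mass, rt window +/- ``rt_window_frac`` of the center rt — a
flat-kernel mean-shift with per-point relative windows.  Converged
centers closer than half a window in both dimensions are merged (the
center capturing more points wins; ties go to the lower mass, then the
lower rt).  Each point is then assigned to the admissible center with
the smallest window-normalized distance, centers are recomputed once
from their assigned members, and members that fall outside the window
of the recomputed center are dropped.  Only clusters with at least two
members are kept in the study-wide cluster list.

The procedure is deterministic: points are sorted by (mass, rt) before
seeding and all tie-breaks are total orders.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin

from .io_formats import PeptideRecord


@dataclass(frozen=True)
class FeatureCluster:
    """A harmonized cross-run feature.

    ``members`` are (sample_id, record_index) references into the
    calibrated per-sample record lists.
    """

    cluster_id: str
    center_mass: float
    center_rt: float
    members: tuple[tuple[str, int], ...]

    @property
    def member_count(self) -> int:
        return len(self.members)


class FeatureClusterer(BaseEstimator, ClusterMixin):
    """Mean-shift style clusterer with relative mass/rt windows.

    Parameters
    ----------
    mass_window_ppm : float
        Half-width of the mass window in ppm of the center mass.
    rt_window_frac : float
        Half-width of the rt window as a fraction of the center rt.
    max_iter : int
        Maximum center-update iterations.
    tol : float
        Convergence tolerance on center movement, in window-normalized
        units.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (k, 2)
        Final (mass, rt) centers, ordered by (mass, rt).
    labels_ : ndarray of shape (n,)
        Cluster index per input point; -1 for points left unassigned
        after the window-containment check.
    """

    def __init__(
        self,
        mass_window_ppm: float = 5.0,
        rt_window_frac: float = 0.05,
        max_iter: int = 50,
        tol: float = 1e-6,
    ):
        self.mass_window_ppm = mass_window_ppm
        self.rt_window_frac = rt_window_frac
        self.max_iter = max_iter
        self.tol = tol

    # -- window helpers ----------------------------------------------------
    def _windows(self, mass, rt):
        return mass * self.mass_window_ppm * 1e-6, rt * self.rt_window_frac

    def _members_in_window(self, masses, rts, cm, crt):
        wm, wr = self._windows(cm, crt)
        lo = np.searchsorted(masses, cm - wm, side="left")
        hi = np.searchsorted(masses, cm + wm, side="right")
        sel = np.abs(rts[lo:hi] - crt) <= wr
        return lo + np.flatnonzero(sel)

    def fit(self, X, y=None):
        if self.mass_window_ppm <= 0 or self.rt_window_frac <= 0:
            raise ValueError("windows must be positive")
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of (mass, rt)")
        n = X.shape[0]
        if n == 0:
            self.cluster_centers_ = np.empty((0, 2))
            self.labels_ = np.empty(0, dtype=int)
            self._order = np.empty(0, dtype=int)
            return self

        # deterministic seeding: sort by (mass, rt)
        order = np.lexsort((X[:, 1], X[:, 0]))
        masses = X[order, 0]
        rts = X[order, 1]

        centers = np.column_stack([masses, rts]).copy()
        for _ in range(self.max_iter):
            moved = 0.0
            for i in range(centers.shape[0]):
                cm, crt = centers[i]
                idx = self._members_in_window(masses, rts, cm, crt)
                if idx.size == 0:
                    continue
                nm = masses[idx].mean()
                nrt = rts[idx].mean()
                wm, wr = self._windows(cm, crt)
                moved = max(moved, abs(nm - cm) / wm, abs(nrt - crt) / wr)
                centers[i] = (nm, nrt)
            if moved < self.tol:
                break

        # point count captured by each converged center
        counts = np.array(
            [
                self._members_in_window(masses, rts, cm, crt).size
                for cm, crt in centers
            ]
        )

        # deduplicate identical centers, then merge near-duplicates:
        # centers closer than half a window in BOTH dimensions collapse
        # onto the one capturing more points (ties: lower mass, lower rt)
        uniq, uidx = np.unique(centers, axis=0, return_index=True)
        ucounts = counts[uidx]
        rank = np.lexsort((uniq[:, 1], uniq[:, 0], -ucounts))
        kept_mass: list[float] = []
        kept_rt: list[float] = []
        for j in rank:
            cm, crt = uniq[j]
            if kept_mass:
                km = np.asarray(kept_mass)
                kr = np.asarray(kept_rt)
                wm = km * self.mass_window_ppm * 1e-6 * 0.5
                wr = kr * self.rt_window_frac * 0.5
                if np.any((np.abs(km - cm) < wm) & (np.abs(kr - crt) < wr)):
                    continue
            kept_mass.append(float(cm))
            kept_rt.append(float(crt))
        kept = np.column_stack([kept_mass, kept_rt])
        # canonical center order
        kept = kept[np.lexsort((kept[:, 1], kept[:, 0]))]

        # assign each point to the admissible center with the smallest
        # window-normalized distance (ties: lower center mass, then rt —
        # already the iteration order)
        labels_sorted = np.full(n, -1, dtype=int)
        km, kr = kept[:, 0], kept[:, 1]
        kwm = km * self.mass_window_ppm * 1e-6
        kwr = kr * self.rt_window_frac
        for p in range(n):
            dm = np.abs(km - masses[p])
            dr = np.abs(kr - rts[p])
            ok = (dm <= kwm) & (dr <= kwr)
            if not ok.any():
                continue
            d = np.where(ok, np.hypot(dm / kwm, dr / kwr), np.inf)
            labels_sorted[p] = int(np.argmin(d))  # argmin keeps first = lowest (mass, rt)

        # recompute centers once from assigned members, then drop members
        # violating the window of the recomputed center
        final_centers = kept.copy()
        for c in range(kept.shape[0]):
            idx = np.flatnonzero(labels_sorted == c)
            if idx.size:
                final_centers[c] = (masses[idx].mean(), rts[idx].mean())
        for c in range(final_centers.shape[0]):
            idx = np.flatnonzero(labels_sorted == c)
            if not idx.size:
                continue
            cm, crt = final_centers[c]
            wm, wr = self._windows(cm, crt)
            bad = idx[
                (np.abs(masses[idx] - cm) > wm) | (np.abs(rts[idx] - crt) > wr)
            ]
            labels_sorted[bad] = -1

        # relabel in center order, dropping empty clusters
        occupied = np.unique(labels_sorted[labels_sorted >= 0])
        remap = {int(old): new for new, old in enumerate(occupied)}
        labels_final = np.array(
            [remap.get(int(l), -1) for l in labels_sorted], dtype=int
        )
        self.cluster_centers_ = final_centers[occupied]
        labels = np.full(n, -1, dtype=int)
        labels[order] = labels_final
        self.labels_ = labels
        return self

    def fit_predict(self, X, y=None):
        return self.fit(X).labels_


def build_clusters(
    records_by_sample: dict[str, list[PeptideRecord]],
    mass_window_ppm: float = 5.0,
    rt_window_frac: float = 0.05,
    max_iter: int = 50,
    tol: float = 1e-6,
) -> list[FeatureCluster]:
    """Cluster all samples' calibrated records into candidate clusters.

    Returns every occupied cluster (including singletons); apply
    :func:`filter_min_members` to obtain the retained cluster list.
    Cluster ids here are provisional; they are reassigned sequentially
    after filtering.
    """
    refs: list[tuple[str, int]] = []
    points: list[tuple[float, float]] = []
    for sample_id in sorted(records_by_sample):
        for i, rec in enumerate(records_by_sample[sample_id]):
            refs.append((sample_id, i))
            points.append((rec.measured_mass, rec.rt))
    if not points:
        return []
    clusterer = FeatureClusterer(
        mass_window_ppm=mass_window_ppm,
        rt_window_frac=rt_window_frac,
        max_iter=max_iter,
        tol=tol,
    )
    labels = clusterer.fit_predict(np.asarray(points))
    clusters: list[FeatureCluster] = []
    for c, center in enumerate(clusterer.cluster_centers_):
        member_idx = np.flatnonzero(labels == c)
        members = tuple(refs[int(i)] for i in member_idx)
        clusters.append(
            FeatureCluster(
                cluster_id=f"tmp{c:06d}",
                center_mass=float(center[0]),
                center_rt=float(center[1]),
                members=members,
            )
        )
    _check_containment(clusters, records_by_sample, mass_window_ppm, rt_window_frac)
    return clusters


def filter_min_members(
    clusters: list[FeatureCluster], min_members: int = 2
) -> list[FeatureCluster]:
    """Keep clusters with at least ``min_members`` members (default 2)
    and reassign sequential cluster ids; order is preserved."""
    kept = [c for c in clusters if c.member_count >= min_members]
    return [
        replace(c, cluster_id=f"C{i:06d}") for i, c in enumerate(kept, start=1)
    ]


def _check_containment(
    clusters: list[FeatureCluster],
    records_by_sample: dict[str, list[PeptideRecord]],
    mass_window_ppm: float,
    rt_window_frac: float,
) -> None:
    """Post-hoc window-containment assertion, run on every build."""
    for c in clusters:
        wm = c.center_mass * mass_window_ppm * 1e-6
        wr = c.center_rt * rt_window_frac
        for sample_id, idx in c.members:
            rec = records_by_sample[sample_id][idx]
            if abs(rec.measured_mass - c.center_mass) > wm * (1 + 1e-9) or abs(
                rec.rt - c.center_rt
            ) > wr * (1 + 1e-9):
                raise AssertionError(
                    f"cluster {c.cluster_id}: member {(sample_id, idx)} "
                    "violates the window invariant"
                )
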