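"""Community-wide isotopic niche metrics (Layman metrics) per area.

Four descriptors of a multi-species community in (delta13C, delta15N)
space:

    TA  total area of the convex hull over species positions [permil^2]
    NR  nitrogen range, max - min delta15N                   [permil]
    CR  carbon range, max - min delta13C                     [permil]
    CD  mean Euclidean distance to the centroid              [permil]

The Bayesian version evaluates the four metrics on every posterior draw
of the species mean vectors, so each metric gets a full posterior that
propagates per-species uncertainty (small-n species widen the community
posterior rather than being ignored).  The hull is built over species
posterior mean vectors per draw; an individual-based CD variant (each
fish against the community centroid) is available because CD is sometimes
defined over individuals.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .ellipses import NichePosterior
from .records import ConfigurationError, IsotopeRecord, logger

#: slack for the exact geometric bound TA <= NR * CR
_BOX_TOL = 1e-9


# ---------------------------------------------------------------------------
# deterministic geometry
# ---------------------------------------------------------------------------

def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array of (d13C, d15N)")
    return pts


def convex_hull(points) -> np.ndarray:
    """Hull vertices in counterclockwise order (Andrew's monotone chain).

    Collinear points on an edge are dropped; for fully collinear input the
    returned "hull" is the degenerate two-point segment.
    """
    pts = _as_points(points)
    uniq = np.unique(pts, axis=0)
    if len(uniq) <= 2:
        return uniq
    pts_sorted = uniq[np.lexsort((uniq[:, 1], uniq[:, 0]))]

    def build(seq):
        chain = []
        for p in seq:
            while len(chain) >= 2:
                o, a = chain[-2], chain[-1]
                if (a[0] - o[0]) * (p[1] - o[1]) - (a[1] - o[1]) * (p[0] - o[0]) <= 0:
                    chain.pop()
                else:
                    break
            chain.append(p)
        return chain

    lower = build(pts_sorted)
    upper = build(pts_sorted[::-1])
    hull = np.array(lower[:-1] + upper[:-1])
    if len(hull) < 3:  # all collinear
        return np.array([pts_sorted[0], pts_sorted[-1]])
    return hull


def shoelace_area(vertices) -> float:
    """Polygon area by the shoelace formula (vertices in order)."""
    v = _as_points(vertices)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def convex_hull_area(points) -> float:
    """Area of the convex hull; 0 for collinear input; requires >= 3 points."""
    pts = _as_points(points)
    if len(pts) < 3:
        raise ValueError(f"convex hull area needs >= 3 points, got {len(pts)}")
    hull = convex_hull(pts)
    if len(hull) < 3:
        return 0.0
    return shoelace_area(hull)


def nitrogen_range(points) -> float:
    """Max - min delta15N across the community (>= 2 points)."""
    pts = _as_points(points)
    if len(pts) < 2:
        raise ValueError("nitrogen range needs >= 2 points")
    return float(pts[:, 1].max() - pts[:, 1].min())


def carbon_range(points) -> float:
    """Max - min delta13C across the community (>= 2 points)."""
    pts = _as_points(points)
    if len(pts) < 2:
        raise ValueError("carbon range needs >= 2 points")
    return float(pts[:, 0].max() - pts[:, 0].min())


def centroid_distance(points) -> float:
    """Mean Euclidean distance from each point to the arithmetic centroid."""
    pts = _as_points(points)
    if len(pts) < 2:
        raise ValueError("centroid distance needs >= 2 points")
    centroid = pts.mean(axis=0)
    return float(np.linalg.norm(pts - centroid, axis=1).mean())


# ---------------------------------------------------------------------------
# posterior community metrics
# ---------------------------------------------------------------------------

@dataclass(slots=True)
class CommunityMetricsPosterior:
    """Posterior draws of TA, NR, CR, CD for one area's community.

    ``ta_draws`` is None when fewer than 3 species are available (the hull
    is undefined); NR/CR/CD are still computed and the condition flagged.
    """

    area: str
    species: list[str]
    nr_draws: np.ndarray
    cr_draws: np.ndarray
    cd_draws: np.ndarray
    ta_draws: np.ndarray | None = None
    cd_mode: str = "species_mean"

    def __post_init__(self):
        nd = len(self.nr_draws)
        arrays = [self.cr_draws, self.cd_draws] + ([self.ta_draws] if self.ta_draws is not None else [])
        if any(len(a) != nd for a in arrays):
            raise ValueError("metric draw arrays must share length n_draws")
        for name, a in (("NR", self.nr_draws), ("CR", self.cr_draws), ("CD", self.cd_draws)):
            if np.any(a < 0):
                raise ValueError(f"{name} draws must be non-negative")
        if self.ta_draws is not None:
            if np.any(self.ta_draws < 0):
                raise ValueError("TA draws must be non-negative")
            # the hull lies inside its bounding box, exactly
            if np.any(self.ta_draws > self.nr_draws * self.cr_draws + _BOX_TOL):
                raise ValueError("TA exceeds NR * CR on some draw")

    @property
    def n_draws(self) -> int:
        return len(self.nr_draws)

    def draws(self, metric: str) -> np.ndarray | None:
        return {"TA": self.ta_draws, "NR": self.nr_draws,
                "CR": self.cr_draws, "CD": self.cd_draws}[metric]

    def summary(self) -> dict:
        out = {"area": self.area, "species": list(self.species),
               "n_draws": self.n_draws, "cd_mode": self.cd_mode}
        for m in ("TA", "NR", "CR", "CD"):
            d = self.draws(m)
            if d is None:
                out[m] = None
                continue
            q = np.percentile(d, [2.5, 25, 50, 75, 97.5])
            out[m] = {"median": float(q[2]),
                      "ci50": [float(q[1]), float(q[3])],
                      "ci95": [float(q[0]), float(q[4])]}
        return out


def community_posterior(area: str,
                        posteriors: Sequence[NichePosterior],
                        records: Sequence[IsotopeRecord] | None = None,
                        cd_mode: str = "species_mean") -> CommunityMetricsPosterior:
    """Community metric posteriors from per-species niche posteriors.

    For each draw index d the species posterior mean vectors {mu_s^(d)}
    form the community point set; TA/NR/CR/CD are evaluated on it.  With
    fewer than 3 species TA is unavailable (flagged; NR/CR/CD still
    computed).  ``cd_mode='individual'`` measures CD as the mean distance
    of the area's fish to the draw's community centroid (requires
    ``records``).
    """
    if len(posteriors) < 2:
        raise ConfigurationError(f"area {area}: need >= 2 species posteriors")
    n_draws = {p.n_draws for p in posteriors}
    if len(n_draws) != 1:
        raise ConfigurationError(f"area {area}: mismatched n_draws {sorted(n_draws)}")
    if cd_mode not in ("species_mean", "individual"):
        raise ConfigurationError(f"unknown cd_mode {cd_mode!r}")

    species = [p.label for p in posteriors]
    mus = np.stack([p.mu_draws for p in posteriors], axis=1)  # (draws, S, 2)

    nr = mus[:, :, 1].max(axis=1) - mus[:, :, 1].min(axis=1)
    cr = mus[:, :, 0].max(axis=1) - mus[:, :, 0].min(axis=1)

    centroids = mus.mean(axis=1)  # (draws, 2)
    if cd_mode == "species_mean":
        cd = np.linalg.norm(mus - centroids[:, None, :], axis=2).mean(axis=1)
    else:
        if not records:
            raise ConfigurationError("cd_mode='individual' requires isotope records")
        xy = np.array([[r.d13c, r.d15n] for r in records if r.area == area])
        if len(xy) == 0:
            raise ConfigurationError(f"no records for area {area}")
        diff = xy[None, :, :] - centroids[:, None, :]
        cd = np.linalg.norm(diff, axis=2).mean(axis=1)

    ta = None
    if len(posteriors) >= 3:
        ta = np.empty(len(mus))
        for d in range(len(mus)):
            ta[d] = convex_hull_area(mus[d])
    else:
        logger.warning("area %s: only %d species; TA unavailable", area, len(posteriors))

    return CommunityMetricsPosterior(area=area, species=species, ta_draws=ta,
                                     nr_draws=nr, cr_draws=cr, cd_draws=cd,
                                     cd_mode=cd_mode)


def community_point_estimates(area: str,
                              records: Sequence[IsotopeRecord],
                              hull_over: str = "species_means") -> dict:
    """Deterministic TA/NR/CR/CD from sample means (companion for plots).

    ``hull_over='individuals'`` builds the hull and metrics over the raw
    fish positions instead of species mean points.  NR/CR computed from
    the raw point set and from the hull vertices are asserted identical.
    """
    recs = [r for r in records if r.area == area]
    if not recs:
        raise ConfigurationError(f"no records for area {area}")
    if hull_over == "species_means":
        by_sp: dict[str, list] = {}
        for r in recs:
            by_sp.setdefault(r.species, []).append((r.d13c, r.d15n))
        pts = np.array([np.mean(v, axis=0) for _, v in sorted(by_sp.items())])
        n_species = len(by_sp)
    elif hull_over == "individuals":
        pts = np.array([(r.d13c, r.d15n) for r in recs])
        n_species = len({r.species for r in recs})
    else:
        raise ConfigurationError(f"unknown hull_over {hull_over!r}")

    out = {"area": area, "n_species": n_species, "hull_over": hull_over,
           "NR": nitrogen_range(pts), "CR": carbon_range(pts),
           "CD": centroid_distance(pts)}
    hull = convex_hull(pts)
    # extrema over hull vertices match extrema over the raw point set
    assert abs(nitrogen_range(hull) - out["NR"]) < 1e-12
    assert abs(carbon_range(hull) - out["CR"]) < 1e-12
    out["TA"] = convex_hull_area(pts) if len(pts) >= 3 else None
    return out
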