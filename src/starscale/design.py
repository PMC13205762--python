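"""Nested spatiotemporal sampling designs.

A design describes a site x treatment cross of plots, each carrying the same
set of sampling points laid out on a cross (plus-shaped) grid, a series of
nested area levels (each level's point set strictly contains the previous
one), and an ordered series of monthly time points. The default emulates a
field layout of 21 points per plot sampled over 17 months in a
2-site x 2-treatment cross, i.e. 1,428 samples in total.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["AreaLevel", "SamplingDesign", "make_design", "InvalidDesignError"]


class InvalidDesignError(ValueError):
    """Raised when a sampling design violates its nesting invariants."""


@dataclass(frozen=True)
class AreaLevel:
    """One nested spatial scale: ordinal level, physical area, member points."""

    level: int
    area_m2: float
    point_ids: tuple[str, ...]


@dataclass(frozen=True)
class SamplingDesign:
    """A nested site x treatment x point x time sampling design.

    Attributes
    ----------
    sites, treatments : labels of the crossed plot factors.
    points : DataFrame indexed by point id with columns ``x``, ``y`` (metres).
    area_levels : ordered nested spatial scales (monotone point sets/areas).
    time_points : ordered 1-based month indices.
    """

    sites: tuple[str, ...]
    treatments: tuple[str, ...]
    points: pd.DataFrame = field(repr=False)
    area_levels: tuple[AreaLevel, ...]
    time_points: tuple[int, ...]

    def __post_init__(self) -> None:
        prev: set[str] = set()
        prev_area = 0.0
        for lvl in self.area_levels:
            cur = set(lvl.point_ids)
            if not cur > prev:
                raise InvalidDesignError(
                    f"area level {lvl.level} point set must strictly contain "
                    f"the previous level's"
                )
            if not lvl.area_m2 > prev_area:
                raise InvalidDesignError("area sizes must be strictly increasing")
            prev, prev_area = cur, lvl.area_m2
        unknown = prev - set(self.points.index)
        if unknown:
            raise InvalidDesignError(f"area levels reference unknown points: {unknown}")

    @property
    def n_samples(self) -> int:
        return (
            len(self.sites)
            * len(self.treatments)
            * len(self.points)
            * len(self.time_points)
        )

    @property
    def plots(self) -> list[tuple[str, str]]:
        """All (site, treatment) plot identities."""
        return [(s, t) for s in self.sites for t in self.treatments]

    @property
    def area_sizes(self) -> np.ndarray:
        return np.array([lvl.area_m2 for lvl in self.area_levels], dtype=float)

    def sample_index(self) -> pd.DataFrame:
        """One row per sample: site, treatment, point, time, with unique ids."""
        rows = [
            {
                "sample": f"{s}.{t}.{p}.m{m:02d}",
                "site": s,
                "treatment": t,
                "point": p,
                "time": m,
            }
            for s in self.sites
            for t in self.treatments
            for p in self.points.index
            for m in self.time_points
        ]
        return pd.DataFrame(rows).set_index("sample")


def _cross_coordinates(n_points: int, spacing: float = 1.5) -> pd.DataFrame:
    # Centre point plus four arms filled round-robin at increasing distance.
    coords = [(0.0, 0.0)]
    arms = [(1, 0), (-1, 0), (0, 1), (0, -1)]
    step = 0
    while len(coords) < n_points:
        arm = arms[step % 4]
        d = spacing * (step // 4 + 1)
        coords.append((arm[0] * d, arm[1] * d))
        step += 1
    ids = [f"p{i + 1:02d}" for i in range(n_points)]
    return pd.DataFrame(coords, columns=["x", "y"], index=pd.Index(ids, name="point"))


def _cumulative_partition(n_points: int, n_levels: int) -> list[int]:
    # Strictly increasing cumulative point counts from 1 to n_points.
    raw = np.round(np.linspace(1, n_points, n_levels)).astype(int)
    raw[-1] = n_points  # the outermost level always pools every point
    out: list[int] = []
    for i, c in enumerate(raw):
        lo = (out[-1] + 1) if out else 1
        hi = n_points - (n_levels - 1 - i)
        out.append(int(min(max(c, lo), hi)))
    return out


def make_design(
    n_sites: int = 2,
    n_treatments: int = 2,
    n_points: int = 21,
    n_times: int = 17,
    n_area_levels: int = 5,
    area_sizes: "np.ndarray | list[float] | None" = None,
    level_point_counts: "list[int] | None" = None,
    point_spacing: float = 1.5,
) -> SamplingDesign:
    """Build a nested cross design.

    Points are placed on a plus-shaped grid; nested area levels take the
    ``level_point_counts`` points closest to the centre (default: cumulative
    counts interpolated from 1 to ``n_points``). Default area sizes follow a
    geometric series 1, 4, 16, ... m².

    Raises
    ------
    InvalidDesignError
        If ``n_area_levels > n_points`` or the provided sizes/partition are
        not strictly increasing.
    """
    if n_area_levels > n_points:
        raise InvalidDesignError(
            f"n_area_levels ({n_area_levels}) cannot exceed n_points ({n_points})"
        )
    if min(n_sites, n_treatments, n_points, n_times, n_area_levels) < 1:
        raise InvalidDesignError("all design dimensions must be >= 1")

    points = _cross_coordinates(n_points, spacing=point_spacing)

    if area_sizes is None:
        area_sizes = [4.0**j for j in range(n_area_levels)]
    area_sizes = [float(a) for a in area_sizes]
    if len(area_sizes) != n_area_levels:
        raise InvalidDesignError("area_sizes length must equal n_area_levels")
    if any(b <= a for a, b in zip(area_sizes, area_sizes[1:])):
        raise InvalidDesignError("area_sizes must be strictly increasing")

    if level_point_counts is None:
        level_point_counts = _cumulative_partition(n_points, n_area_levels)
    if len(level_point_counts) != n_area_levels or any(
        b <= a for a, b in zip(level_point_counts, level_point_counts[1:])
    ):
        raise InvalidDesignError("level_point_counts must be strictly increasing")
    if level_point_counts[-1] != n_points:
        raise InvalidDesignError("last area level must contain every point")

    # Nearest-to-centre ordering; ties broken by point id for determinism.
    dist = np.hypot(points["x"], points["y"])
    order = points.index[np.lexsort((points.index, dist))]
    levels = tuple(
        AreaLevel(j + 1, area_sizes[j], tuple(order[: level_point_counts[j]]))
        for j in range(n_area_levels)
    )

    return SamplingDesign(
        sites=tuple(f"site{i + 1}" for i in range(n_sites)),
        treatments=tuple(
            ["fallow", "cropping"][i] if n_treatments == 2 else f"trt{i + 1}"
            for i in range(n_treatments)
        ),
        points=points,
        area_levels=levels,
        time_points=tuple(range(1, n_times + 1)),
    )
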