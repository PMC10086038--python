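"""Planar-gradiometer sensor layouts on the helmet plane.

Only combined-gradiometer sites are modelled: each site carries a pair of
orthogonal planar gradiometers and a 2-D position in a flattened helmet
coordinate frame (unit disk, x > 0 = right hemisphere, y > 0 = anterior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["SensorLayout", "make_layout"]

_GOLDEN = np.pi * (3.0 - np.sqrt(5.0))


@dataclass
class SensorLayout:
    """Sites, gradiometer pairs and the spatial neighbourhood relation.

    Attributes
    ----------
    site_ids : list of str
    pos : (n_sites, 2) float array
        Helmet-plane coordinates on the unit disk.
    pairs : dict
        site_id -> (channel_id_1, channel_id_2).
    neighbor_radius : float
        Two sites are neighbours iff their Euclidean distance is strictly
        below this radius.
    region : list of str
        Coarse anatomical grouping ("occipital" / "parietal" / "frontal"),
        assigned from the anterior-posterior coordinate; used for the
        region-restricted lateralization contrasts.
    """

    site_ids: list
    pos: np.ndarray
    pairs: dict
    neighbor_radius: float
    region: list = field(default_factory=list)

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def ch_names(self) -> list:
        out = []
        for s in self.site_ids:
            out.extend(self.pairs[s])
        return out

    @property
    def hemisphere(self) -> np.ndarray:
        """Per-site label: 'left' iff x < 0, 'right' iff x > 0, else 'midline'."""
        x = self.pos[:, 0]
        lab = np.where(x < 0, "left", np.where(x > 0, "right", "midline"))
        return lab

    def hemisphere_sites(self, side: str) -> np.ndarray:
        """Indices of the sites in one hemisphere."""
        return np.flatnonzero(self.hemisphere == side)

    def adjacency(self) -> np.ndarray:
        """Symmetric boolean (n_sites, n_sites) neighbourhood matrix, no self-edges."""
        d = np.linalg.norm(self.pos[:, None, :] - self.pos[None, :, :], axis=-1)
        adj = d < self.neighbor_radius
        np.fill_diagonal(adj, False)
        return adj

    def to_json(self, path) -> None:
        obj = {
            "site_ids": list(self.site_ids),
            "pos": np.asarray(self.pos).tolist(),
            "pairs": {k: list(v) for k, v in self.pairs.items()},
            "neighbor_radius": float(self.neighbor_radius),
            "region": list(self.region),
        }
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "SensorLayout":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(
            site_ids=obj["site_ids"],
            pos=np.asarray(obj["pos"], dtype=float),
            pairs={k: tuple(v) for k, v in obj["pairs"].items()},
            neighbor_radius=obj["neighbor_radius"],
            region=obj.get("region", []),
        )


def _half_disk_points(m: int) -> np.ndarray:
    """Quasi-uniform points on the right half of the unit disk (sunflower spiral)."""
    i = np.arange(m)
    r = np.sqrt((i + 0.5) / m)
    theta = (i * _GOLDEN) % np.pi - np.pi / 2.0  # (-pi/2, pi/2): x >= 0
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def _region_of(y: float) -> str:
    if y < -0.45:
        return "occipital"
    if y < 0.1:
        return "parietal"
    return "frontal"


def make_layout(
    n_sites: int = 102,
    symmetric: bool = True,
    seed: int = 0,
    neighbor_radius: float | None = None,
    jitter: float = 0.0,
) -> SensorLayout:
    """Build a synthetic combined-gradiometer layout.

    With ``symmetric=True`` the layout is mirror-symmetric about x = 0; for
    odd ``n_sites`` the extra site sits on the midline. ``neighbor_radius``
    defaults to ``sqrt(7 / n_sites)``, which gives on average about six
    neighbours per site for the 102-site default.
    """
    if n_sites < 2:
        raise ValueError(f"n_sites must be >= 2, got {n_sites}")
    rng = np.random.default_rng(seed)
    if symmetric:
        m = n_sites // 2
        right = _half_disk_points(m)
        # keep strictly off the midline so hemisphere labels are unambiguous
        right[:, 0] = np.maximum(right[:, 0], 0.04)
        if jitter:
            right = right + rng.normal(0.0, jitter, right.shape)
            right[:, 0] = np.maximum(right[:, 0], 0.04)
        left = right * np.array([-1.0, 1.0])
        pos = np.concatenate([left, right], axis=0)
        if n_sites % 2:
            pos = np.concatenate([pos, [[0.0, float(rng.uniform(-0.8, 0.8))]]], axis=0)
    else:
        i = np.arange(n_sites)
        r = np.sqrt((i + 0.5) / n_sites)
        theta = i * _GOLDEN
        pos = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
        if jitter:
            pos = pos + rng.normal(0.0, jitter, pos.shape)
    # stable ordering: posterior-to-anterior, left-to-right
    order = np.lexsort((pos[:, 0], pos[:, 1]))
    pos = pos[order]
    site_ids = [f"S{i:03d}" for i in range(n_sites)]
    pairs = {s: (f"{s}a", f"{s}b") for s in site_ids}
    if neighbor_radius is None:
        neighbor_radius = float(np.sqrt(7.0 / n_sites))
    region = [_region_of(y) for y in pos[:, 1]]
    return SensorLayout(
        site_ids=site_ids,
        pos=pos,
        pairs=pairs,
        neighbor_radius=neighbor_radius,
        region=region,
    )
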