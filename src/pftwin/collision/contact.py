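"""Contact patches and contact-episode bookkeeping.

A contact *episode* starts when a patch first appears and ends at
separation.  The normal approach rate at the first detecting step is
latched as ``delta_dot0`` and held constant for the whole episode — the
dissipative term of the Flores model is normalized by it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

__all__ = ["ContactPatch", "EpisodeTracker"]


@dataclass
class ContactPatch:
    """One detected contact between the femoral surface and the patella.

    ``normal`` is unit length and points from the femur surface toward the
    patella; ``delta`` (indentation) is non-negative; rates are positive
    during approach/compression.
    """

    point: np.ndarray              # world, m
    normal: np.ndarray             # unit, femur -> patella
    delta: float                   # m
    delta_dot: float = 0.0         # m/s
    delta_dot0: Optional[float] = None   # latched at episode start
    contour: Optional[list] = None       # closed polyline(s), world coords
    left_domain: bool = False      # analytic backend: sphere left the fit domain
    deep: bool = False             # center passed below the surface
    episode_id: int = -1

    def __post_init__(self):
        self.point = np.asarray(self.point, float)
        self.normal = np.asarray(self.normal, float)
        n = np.linalg.norm(self.normal)
        if abs(n - 1.0) > 1e-9:
            self.normal = self.normal / n
        if self.delta < 0:
            raise ValueError("indentation must be >= 0")


@dataclass
class _Episode:
    eid: int
    point: np.ndarray
    delta_dot0: Optional[float]
    t_start: float
    active: bool = True


class EpisodeTracker:
    """Match patches across steps and latch ``delta_dot0`` per episode.

    Patches are matched to open episodes by proximity of their contact
    points (``match_radius``); unmatched patches open new episodes, and
    open episodes with no patch this step are closed.  If the approach
    rate at first detection is not clearly positive — the simulation
    starts already in contact, or the episode opens grazing/separating —
    the dissipative normalization is disabled for that episode
    (``delta_dot0 = None``, pure elastic) and the event is recorded:
    normalizing by a near-zero or negative impact speed would make the
    damping factor blow up or flip sign.
    """

    def __init__(self, match_radius: float = 0.01, zero_tol: float = 1e-3):
        self.match_radius = float(match_radius)
        self.zero_tol = float(zero_tol)
        self._episodes: List[_Episode] = []
        self._next_id = 0
        self.log: List[dict] = []

    @property
    def open_episodes(self) -> List[_Episode]:
        return [e for e in self._episodes if e.active]

    def update(self, patches: List[ContactPatch], t: float = 0.0) -> List[ContactPatch]:
        """Assign episode ids and ``delta_dot0`` to this step's patches."""
        open_eps = self.open_episodes
        used = set()
        for p in patches:
            best, best_d = None, self.match_radius
            for e in open_eps:
                if e.eid in used:
                    continue
                d = float(np.linalg.norm(e.point - p.point))
                if d < best_d:
                    best, best_d = e, d
            if best is None:
                dd0 = float(p.delta_dot)
                if dd0 <= self.zero_tol:
                    dd0 = None
                    self.log.append({"t": t, "event": "episode_starts_in_contact"})
                best = _Episode(self._next_id, p.point.copy(), dd0, t)
                self._next_id += 1
                self._episodes.append(best)
            used.add(best.eid)
            best.point = p.point.copy()
            p.episode_id = best.eid
            p.delta_dot0 = best.delta_dot0
        for e in open_eps:
            if e.eid not in used:
                e.active = False
                self.log.append({"t": t, "event": "separation", "episode": e.eid})
        return patches

    def reset(self) -> None:
        self._episodes.clear()
        self.log.clear()
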