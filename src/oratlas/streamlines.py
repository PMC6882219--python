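"""Streamline sets: polylines in world mm with per-streamline tags."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class StreamlineSet:
    """A collection of streamlines (polylines) in RAS+ world mm.

    Each streamline is an ``(n_points, 3)`` float array with ``n_points >= 2``.
    ``tags`` carries one dict per streamline with free-form keys; the pipeline
    uses ``division`` (``"ORu"``/``"ORl"``), ``subject`` (int) and ``side``
    (``"left"``/``"right"``).
    """

    streamlines: list[np.ndarray]
    tags: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        cleaned = []
        for sl in self.streamlines:
            arr = np.asarray(sl, dtype=float)
            if arr.ndim != 2 or arr.shape[1] != 3 or arr.shape[0] < 2:
                raise ValueError("each streamline must be an (n>=2, 3) array")
            if not np.all(np.isfinite(arr)):
                raise ValueError("streamline coordinates must be finite")
            cleaned.append(arr)
        self.streamlines = cleaned
        if not self.tags:
            self.tags = [{} for _ in cleaned]
        if len(self.tags) != len(cleaned):
            raise ValueError("tags length must match streamline count")

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    @property
    def points(self) -> np.ndarray:
        """All vertices stacked into one (N, 3) array."""
        if not self.streamlines:
            return np.empty((0, 3))
        return np.concatenate(self.streamlines, axis=0)

    def lengths_mm(self) -> np.ndarray:
        """Arc length of every streamline in mm."""
        return np.array(
            [np.sum(np.linalg.norm(np.diff(sl, axis=0), axis=1)) for sl in self.streamlines]
        )

    def select(self, **criteria) -> "StreamlineSet":
        """Subset whose tags match every keyword (e.g. ``division="ORu"``)."""
        keep = [
            i
            for i, t in enumerate(self.tags)
            if all(t.get(k) == v for k, v in criteria.items())
        ]
        return StreamlineSet(
            [self.streamlines[i] for i in keep], [dict(self.tags[i]) for i in keep]
        )

    def with_tag(self, **updates) -> "StreamlineSet":
        """Copy with tag keys added/overwritten on every streamline."""
        return StreamlineSet(
            [sl.copy() for sl in self.streamlines],
            [{**t, **updates} for t in self.tags],
        )

    def map_points(self, fn) -> "StreamlineSet":
        """Apply ``fn((n,3) array) -> (n,3) array`` to every streamline."""
        return StreamlineSet([np.asarray(fn(sl), float) for sl in self.streamlines],
                             [dict(t) for t in self.tags])

    def divisions(self) -> set:
        return {t.get("division") for t in self.tags}
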