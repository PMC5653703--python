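"""Region-of-interest bookkeeping.

The default atlas is the 14-structure subcortical set used throughout the
package: accumbens, amygdala, caudate, hippocampus, putamen, pallidum and
thalamus in each hemisphere, ordered left hemisphere first so that homotopic
(left/right mirror) pairs sit on the quadrant diagonals of an adjacency
matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ParameterError

SUBCORTICAL_STRUCTURES: tuple[str, ...] = (
    "Accumbens",
    "Amygdala",
    "Caudate",
    "Hippocampus",
    "Putamen",
    "Pallidum",
    "Thalamus",
)


@dataclass(frozen=True)
class RoiSet:
    """An ordered set of ROI labels plus its homotopic pairing.

    Parameters
    ----------
    labels
        Unique ROI names; their order fixes row/column order everywhere.
    homotopic_pairs
        ``(left_index, right_index)`` tuples; each index may appear in at
        most one pair.
    """

    labels: tuple[str, ...]
    homotopic_pairs: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        d = len(self.labels)
        if d < 2:
            raise ParameterError("an RoiSet needs at least two ROIs")
        if len(set(self.labels)) != d:
            raise ParameterError("ROI labels must be unique")
        seen: set[int] = set()
        for i, j in self.homotopic_pairs:
            for k in (i, j):
                if not (0 <= k < d):
                    raise ParameterError(f"homotopic index {k} out of range for d={d}")
                if k in seen:
                    raise ParameterError(f"ROI index {k} appears in more than one homotopic pair")
                seen.add(k)

    @property
    def n_rois(self) -> int:
        return len(self.labels)

    @property
    def n_possible_edges(self) -> int:
        """Number of distinct ROI pairs, d(d-1)/2 — the count of
        connections a full conditional-independence model must estimate."""
        d = len(self.labels)
        return d * (d - 1) // 2

    def pair_labels(self, i: int, j: int) -> tuple[str, str]:
        return self.labels[i], self.labels[j]

    def is_homotopic(self, i: int, j: int) -> bool:
        return (i, j) in self.homotopic_pairs or (j, i) in self.homotopic_pairs


def default_roi_set() -> RoiSet:
    """The 14-ROI subcortical set: 7 left-hemisphere structures followed by
    their right-hemisphere mirrors, giving 7 homotopic pairs ``(i, i+7)``."""
    labels = tuple(f"L_{s}" for s in SUBCORTICAL_STRUCTURES) + tuple(
        f"R_{s}" for s in SUBCORTICAL_STRUCTURES
    )
    pairs = tuple((i, i + 7) for i in range(7))
    return RoiSet(labels=labels, homotopic_pairs=pairs)
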