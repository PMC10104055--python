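"""Chromatin-feature predictor contract and the track-backed synthetic predictor.

The pipeline only assumes an object with ``n_features`` and
``predict_window(chrom, start, end) -> (F,) vector``: for the real method
that would be a trained CNN scoring the window for F epigenetic marks (2002
in the published model). The packaged implementation is ``TrackPredictor``,
which reads ground-truth piecewise-constant signal tracks and returns the
per-feature mean signal over the window — deterministic, linear in the
tracks, and resolution-independent, which is exactly what the downstream
tensor construction needs for testing.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SignalTrackSet", "TrackPredictor", "write_bedgraph", "read_bedgraph_dir"]


class SignalTrackSet:
    """Per-chromosome, per-feature piecewise-constant non-negative signal.

    Stored run-length encoded: for each chromosome a sorted breakpoint vector
    ``edges`` (starting at 0, ending at the chromosome length) and a values
    matrix of shape (F, len(edges) − 1). A cumulative integral per feature is
    precomputed so window means cost O(log n_segments).
    """

    def __init__(self, n_features: int):
        self.n_features = int(n_features)
        self._edges: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        self._cum: dict[str, np.ndarray] = {}

    @property
    def chroms(self) -> list[str]:
        return sorted(self._edges)

    def chrom_length(self, chrom: str) -> int:
        return int(self._edges[chrom][-1])

    def set_chrom(self, chrom: str, edges: np.ndarray, values: np.ndarray) -> None:
        edges = np.asarray(edges, dtype=np.int64)
        values = np.asarray(values, dtype=float)
        if values.shape != (self.n_features, len(edges) - 1):
            raise ValueError(
                f"values shape {values.shape} inconsistent with "
                f"({self.n_features}, {len(edges) - 1})"
            )
        if edges[0] != 0 or np.any(np.diff(edges) <= 0):
            raise ValueError("edges must start at 0 and be strictly increasing")
        if np.any(values < 0) or not np.all(np.isfinite(values)):
            raise ValueError("track signal must be finite and non-negative")
        self._edges[chrom] = edges
        self._values[chrom] = values
        seg = np.diff(edges).astype(float)
        cum = np.zeros((self.n_features, len(edges)))
        np.cumsum(values * seg[None, :], axis=1, out=cum[:, 1:])
        self._cum[chrom] = cum

    @classmethod
    def from_intervals(
        cls,
        n_features: int,
        chrom_sizes: dict[str, int],
        intervals: list[tuple[str, int, int, int, float]],
    ) -> "SignalTrackSet":
        """Build tracks from additive (chrom, start, end, feature, amplitude) blocks."""
        ts = cls(n_features)
        by_chrom: dict[str, list] = {c: [] for c in chrom_sizes}
        for chrom, start, end, feat, amp in intervals:
            by_chrom[chrom].append((start, end, feat, amp))
        for chrom, size in chrom_sizes.items():
            blocks = by_chrom[chrom]
            cuts = {0, size}
            for s, e, _f, _a in blocks:
                if not (0 <= s < e <= size):
                    raise ValueError(f"interval [{s},{e}) outside {chrom} (len {size})")
                cuts.add(s)
                cuts.add(e)
            edges = np.array(sorted(cuts), dtype=np.int64)
            values = np.zeros((n_features, len(edges) - 1))
            for s, e, f, a in blocks:
                i0 = np.searchsorted(edges, s)
                i1 = np.searchsorted(edges, e)
                values[f, i0:i1] += a
            ts.set_chrom(chrom, edges, values)
        return ts

    def _integral(self, chrom: str, pos: float) -> np.ndarray:
        """Per-feature integral of the signal over [0, pos)."""
        edges = self._edges[chrom]
        cum = self._cum[chrom]
        k = int(np.searchsorted(edges, pos, side="right") - 1)
        k = min(k, len(edges) - 2)
        return cum[:, k] + self._values[chrom][:, k] * (pos - edges[k])

    def window_mean(self, chrom: str, start: int, end: int) -> np.ndarray:
        if chrom not in self._edges:
            raise KeyError(f"chromosome {chrom!r} has no tracks")
        length = self.chrom_length(chrom)
        if not (0 <= start < end <= length):
            raise ValueError(
                f"window [{start}, {end}) outside {chrom} (length {length})"
            )
        return (self._integral(chrom, end) - self._integral(chrom, start)) / (end - start)


class TrackPredictor:
    """Deterministic predictor returning mean track signal per feature.

    Strand-agnostic by design: orientation of upstream/downstream is applied
    where the positional summaries are built, not here.
    """

    def __init__(self, tracks: SignalTrackSet):
        self.tracks = tracks

    @property
    def n_features(self) -> int:
        return self.tracks.n_features

    def chrom_length(self, chrom: str) -> int:
        return self.tracks.chrom_length(chrom)

    def predict_window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Mean signal per feature over [start, end); errors outside the chromosome."""
        return self.tracks.window_mean(chrom, start, end)

    def predict_tiled(self, chrom: str, start: int, end: int, window_bp: int) -> np.ndarray:
        """Tile [start, end) into ceil((end−start)/window_bp) windows.

        Returns an (n_windows, F) array in genomic order; the last window is
        truncated at ``end``.
        """
        if window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if end <= start:
            raise ValueError("empty region")
        starts = np.arange(start, end, window_bp)
        return np.stack(
            [self.predict_window(chrom, int(s), int(min(s + window_bp, end))) for s in starts]
        )


# ---------------------------------------------------------------------------
# BedGraph serialization of the synthetic tracks


def write_bedgraph(tracks: SignalTrackSet, feature: int, path: str) -> None:
    """Write one feature's track as BedGraph (zero runs included)."""
    with open(path, "w") as fh:
        for chrom in tracks.chroms:
            edges = tracks._edges[chrom]
            values = tracks._values[chrom][feature]
            for k in range(len(edges) - 1):
                fh.write(f"{chrom}\t{edges[k]}\t{edges[k + 1]}\t{values[k]:.8g}\n")


def read_bedgraph_dir(paths: list[str], chrom_sizes: dict[str, int]) -> SignalTrackSet:
    """Read one BedGraph per feature (in list order) into a track set."""
    intervals = []
    for feat, path in enumerate(paths):
        with open(path) as fh:
            for lineno, raw in enumerate(fh, start=1):
                line = raw.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                fields = line.split("\t")
                if len(fields) != 4:
                    raise ValueError(f"{path}:{lineno}: expected 4 columns")
                chrom, s, e, v = fields
                value = float(v)
                if value != 0.0:
                    intervals.append((chrom, int(s), int(e), feat, value))
    return SignalTrackSet.from_intervals(len(paths), chrom_sizes, intervals)
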