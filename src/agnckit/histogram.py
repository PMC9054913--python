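"""TCSPC decay histograms and their plain-text serialization.

A :class:`DecayHistogram` is one binned photon-arrival-time trace — counts per
time channel for a single emission wavelength, temperature and polarization.
Files are two-column TSV with ``#``-prefixed header lines carrying the
metadata, so traces remain diffable and instrument-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

__all__ = ["DecayHistogram"]

# metadata keys written to / parsed from the TSV header
_HEADER_KEYS = ("channel_width_ns", "wavelength_nm", "temperature_C", "polarization")


@dataclass
class DecayHistogram:
    """Binned photon counts versus arrival time.

    Parameters
    ----------
    time : ndarray
        Channel times in ns (left edges), strictly increasing, uniform step.
    counts : ndarray
        Non-negative photon counts per channel (float allowed for expected
        curves in noiseless mode).
    channel_width : float
        Channel width in ns.
    metadata : dict
        Free-form; recognised keys: ``wavelength_nm``, ``temperature_C``,
        ``polarization``, ``truth`` (generating ground truth for synthetic
        traces).
    """

    time: np.ndarray
    counts: np.ndarray
    channel_width: float
    metadata: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.time.shape != self.counts.shape:
            raise ValueError("time and counts must have the same length")
        if self.channel_width <= 0:
            raise ValueError("channel_width must be positive")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time axis must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_channels(self) -> int:
        return self.time.size

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())

    def same_axis(self, other: "DecayHistogram", rtol: float = 1e-9) -> bool:
        """True if *other* shares this histogram's time axis."""
        return self.time.shape == other.time.shape and np.allclose(
            self.time, other.time, rtol=rtol, atol=0.0
        )

    # ------------------------------------------------------------------ I/O
    def to_tsv(self, path: str | Path) -> None:
        """Write a two-column TSV with ``#`` metadata header lines."""
        path = Path(path)
        lines = [f"# channel_width_ns\t{self.channel_width!r}"]
        for key in _HEADER_KEYS[1:]:
            if key in self.metadata:
                lines.append(f"# {key}\t{self.metadata[key]}")
        lines.append("# channel_index\tcounts")
        body = "\n".join(
            f"{i}\t{c:.6g}" for i, c in enumerate(self.counts)
        )
        path.write_text("\n".join(lines) + "\n" + body + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DecayHistogram":
        path = Path(path)
        meta: dict[str, Any] = {}
        counts = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                if len(parts) == 2 and parts[0] in _HEADER_KEYS:
                    key, val = parts
                    if key == "polarization":
                        meta[key] = val
                    else:
                        meta[key] = float(val)
                continue
            idx, c = line.split("\t")
            counts.append(float(c))
        if "channel_width_ns" not in meta:
            raise ValueError(f"{path}: missing channel_width_ns header")
        width = meta.pop("channel_width_ns")
        counts_arr = np.asarray(counts)
        time = np.arange(counts_arr.size) * width
        return cls(time=time, counts=counts_arr, channel_width=width, metadata=meta)

    # ------------------------------------------------------------- plotting
    def plot(self, ax=None, log: bool = True, **kwargs):
        """Plot counts vs time (semilog-y by default)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        plotter = ax.semilogy if log else ax.plot
        plotter(self.time, np.maximum(self.counts, 1e-300 if log else 0), **kwargs)
        ax.set_xlabel("time (ns)")
        ax.set_ylabel("counts")
        return ax
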