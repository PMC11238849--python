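"""Spike-train containers, text/HDF5 I/O, population series and surrogates.

A :class:`SpikeTrain` holds the sorted event times (seconds) of one unit
over a fixed recording span; a :class:`SpikeDataset` is a collection of
trains sharing that span.  The module also provides the summed-population
train, time histograms, and the jitter / ISI-shuffle surrogates used as
temporal-variability references.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SpikeTrain",
    "SpikeDataset",
    "HistogramSeries",
    "SpikeFileError",
    "read_spike_trains",
    "write_spike_trains",
    "save_dataset_h5",
    "load_dataset_h5",
    "sum_trains",
    "time_histogram",
    "jitter_surrogate",
    "shuffle_surrogate",
]


class SpikeFileError(ValueError):
    """Malformed spike event file."""


@dataclass(frozen=True)
class SpikeTrain:
    """Sorted spike times of one unit.

    Parameters
    ----------
    unit_id : int
        Integer unit label.
    times : array-like
        Strictly increasing spike times in seconds.
    t_start, t_stop : float
        Recording span in seconds; all times must lie within it.
    """

    unit_id: int
    times: np.ndarray
    t_start: float
    t_stop: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        if self.t_stop < self.t_start:
            raise ValueError("t_stop must be >= t_start")
        if t.size:
            if t[0] < self.t_start or t[-1] > self.t_stop:
                raise ValueError(
                    f"unit {self.unit_id}: spike times outside span "
                    f"[{self.t_start}, {self.t_stop}]"
                )
            if np.any(np.diff(t) <= 0):
                raise ValueError(
                    f"unit {self.unit_id}: times must be strictly increasing "
                    "(duplicates can be collapsed at read time)"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.times.size)

    @property
    def duration(self) -> float:
        return float(self.t_stop - self.t_start)

    @property
    def rate(self) -> float:
        """Mean firing rate in spikes/s (0 for an empty span)."""
        return self.n_spikes / self.duration if self.duration > 0 else 0.0


@dataclass(frozen=True)
class SpikeDataset:
    """Collection of spike trains sharing one recording span."""

    trains: tuple[SpikeTrain, ...]
    t_start: float = field(default=None)  # type: ignore[assignment]
    t_stop: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        trains = tuple(self.trains)
        object.__setattr__(self, "trains", trains)
        if not trains:
            raise ValueError("dataset must contain at least one train")
        ids = [tr.unit_id for tr in trains]
        if len(set(ids)) != len(ids):
            raise ValueError("unit_ids must be unique")
        t0 = trains[0].t_start if self.t_start is None else self.t_start
        t1 = trains[0].t_stop if self.t_stop is None else self.t_stop
        object.__setattr__(self, "t_start", float(t0))
        object.__setattr__(self, "t_stop", float(t1))
        for tr in trains:
            if tr.t_start != self.t_start or tr.t_stop != self.t_stop:
                raise ValueError("all trains must share the recording span")

    @property
    def duration(self) -> float:
        return float(self.t_stop - self.t_start)

    @property
    def unit_ids(self) -> list[int]:
        return [tr.unit_id for tr in self.trains]

    @property
    def n_units(self) -> int:
        return len(self.trains)

    def __getitem__(self, unit_id: int) -> SpikeTrain:
        for tr in self.trains:
            if tr.unit_id == unit_id:
                return tr
        raise KeyError(f"no unit {unit_id}")

    def __iter__(self):
        return iter(self.trains)


@dataclass(frozen=True)
class HistogramSeries:
    """Binned event counts: ``counts[b]`` events in ``[bin_edges[b], bin_edges[b+1])``."""

    bin_edges: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "bin_edges", np.asarray(self.bin_edges, float))
        object.__setattr__(self, "counts", np.asarray(self.counts, int))
        if self.counts.size != self.bin_edges.size - 1:
            raise ValueError("counts must have len(bin_edges) - 1 entries")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_row(line: str, lineno: int) -> tuple[float, int]:
    parts = line.replace(",", " ").split()
    if len(parts) < 2:
        raise SpikeFileError(f"line {lineno}: expected two columns, got {line!r}")
    try:
        t = float(parts[0])
        u = int(parts[1])
    except ValueError:
        raise SpikeFileError(
            f"line {lineno}: could not parse (time_s, unit_id) from {line!r}"
        ) from None
    if u < 0:
        raise SpikeFileError(f"line {lineno}: unit id must be non-negative")
    return t, u


def read_spike_trains(path, span=None, on_duplicate: str = "raise") -> SpikeDataset:
    """Read a two-column delimited event file (time_s, unit_id).

    Whitespace- or comma-delimited; a single non-numeric header line is
    auto-detected and skipped.  If *span* is omitted it is inferred as
    ``(0, ceil(max time))``.

    Parameters
    ----------
    on_duplicate : {"raise", "collapse"}
        Duplicate timestamps within a unit are rejected by default (they
        corrupt zero-lag correlogram counts) or collapsed to one event.
    """
    if on_duplicate not in ("raise", "collapse"):
        raise ValueError("on_duplicate must be 'raise' or 'collapse'")
    if hasattr(path, "read"):
        lines = path.read().splitlines()
    else:
        with open(path) as fh:
            lines = fh.read().splitlines()
    times: list[float] = []
    units: list[int] = []
    for i, line in enumerate(lines, start=1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        try:
            t, u = _parse_row(line, i)
        except SpikeFileError:
            if i == 1 and not times:  # tolerate a single header line
                continue
            raise
        times.append(t)
        units.append(u)
    if not times:
        raise SpikeFileError("no events in file")
    tarr = np.asarray(times)
    uarr = np.asarray(units)
    if span is None:
        t_start, t_stop = 0.0, float(np.ceil(tarr.max())) if tarr.max() > 0 else 1.0
    else:
        t_start, t_stop = float(span[0]), float(span[1])
        if tarr.min() < t_start or tarr.max() > t_stop:
            raise SpikeFileError(
                f"event time outside explicit span [{t_start}, {t_stop}]"
            )
    trains = []
    for u in np.unique(uarr):
        t = np.sort(tarr[uarr == u])
        if t.size > 1 and np.any(np.diff(t) == 0):
            if on_duplicate == "raise":
                raise SpikeFileError(
                    f"unit {u}: duplicate timestamps (pass on_duplicate='collapse')"
                )
            t = np.unique(t)
        trains.append(SpikeTrain(int(u), t, t_start, t_stop))
    return SpikeDataset(tuple(trains), t_start, t_stop)


def write_spike_trains(dataset: SpikeDataset, path, precision: int = 7) -> None:
    """Write a dataset as two-column text (time_s, unit_id), time-sorted."""
    times = np.concatenate([tr.times for tr in dataset.trains])
    units = np.concatenate(
        [np.full(tr.n_spikes, tr.unit_id, dtype=int) for tr in dataset.trains]
    )
    order = np.argsort(times, kind="stable")
    fh = path if hasattr(path, "write") else open(path, "w")
    try:
        for t, u in zip(times[order], units[order]):
            fh.write(f"{t:.{precision}f} {u}\n")
    finally:
        if not hasattr(path, "write"):
            fh.close()


def save_dataset_h5(dataset: SpikeDataset, path) -> None:
    """Persist a dataset as an HDF5 container with one array per unit."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["t_start"] = dataset.t_start
        f.attrs["t_stop"] = dataset.t_stop
        for tr in dataset.trains:
            f.create_dataset(f"/unit_{tr.unit_id}/times", data=tr.times)


def load_dataset_h5(path) -> SpikeDataset:
    import h5py

    with h5py.File(path, "r") as f:
        t0, t1 = float(f.attrs["t_start"]), float(f.attrs["t_stop"])
        trains = []
        for name in sorted(f.keys(), key=lambda s: int(s.split("_")[1])):
            uid = int(name.split("_")[1])
            trains.append(SpikeTrain(uid, f[name]["times"][...], t0, t1))
    return SpikeDataset(tuple(trains), t0, t1)


# ---------------------------------------------------------------------------
# Population series and surrogates
# ---------------------------------------------------------------------------

def _bare_train(unit_id, times, t_start, t_stop) -> SpikeTrain:
    # Sorted-but-not-strictly-increasing trains (coincidences across units,
    # clipped surrogates) bypass the strict-increase invariant deliberately.
    out = object.__new__(SpikeTrain)
    object.__setattr__(out, "unit_id", unit_id)
    object.__setattr__(out, "times", np.asarray(times, float))
    object.__setattr__(out, "t_start", float(t_start))
    object.__setattr__(out, "t_stop", float(t_stop))
    return out


def sum_trains(dataset: SpikeDataset, unit_id: int = -1) -> SpikeTrain:
    """Merge all trains into one summed population spike train.

    The merged train may contain coincident events from different units;
    ties are kept, so the total count is conserved exactly.
    """
    times = np.sort(np.concatenate([tr.times for tr in dataset.trains]))
    return _bare_train(unit_id, times, dataset.t_start, dataset.t_stop)


def time_histogram(train: SpikeTrain, bin_width: float) -> HistogramSeries:
    """Spike-count time histogram with bins of *bin_width* seconds."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    n_bins = max(1, int(np.ceil(train.duration / bin_width)))
    edges = train.t_start + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(train.times, bins=edges)
    return HistogramSeries(edges, counts)


def jitter_surrogate(train: SpikeTrain, half_width: float, seed: int) -> SpikeTrain:
    """Displace each spike independently, uniform on ±*half_width* seconds.

    Destroys spike timing finer than the jitter scale while preserving the
    count and the coarse rate profile; displaced times are clipped to the
    recording span and re-sorted.
    """
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    rng = np.random.default_rng(seed)
    t = train.times + rng.uniform(-half_width, half_width, size=train.n_spikes)
    t = np.sort(np.clip(t, train.t_start, train.t_stop))
    return _bare_train(train.unit_id, t, train.t_start, train.t_stop)


def shuffle_surrogate(dataset: SpikeDataset, seed: int) -> SpikeDataset:
    """Per unit, permute inter-spike intervals and re-accumulate.

    Preserves each unit's ISI multiset, spike count and first spike time,
    while destroying cross-unit timing relationships.
    """
    rng = np.random.default_rng(seed)
    trains = []
    for tr in dataset.trains:
        if tr.n_spikes <= 2:
            trains.append(tr)
            continue
        isi = np.diff(tr.times)
        t = tr.times[0] + np.concatenate([[0.0], np.cumsum(rng.permutation(isi))])
        # float reordering can overshoot the span by rounding error
        t = np.minimum(t, tr.t_stop)
        trains.append(_bare_train(tr.unit_id, t, tr.t_start, tr.t_stop))
    return SpikeDataset(tuple(trains), dataset.t_start, dataset.t_stop)
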