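"""Transcription read-out, activity summaries, bursts, TF-cluster statistics.

A TU is transcribed at a sampling instant iff at least one ACTIVE TF centre
lies within r_c = 1.8 sigma of the bead centre -- inactive TFs are inert and
never count.  The activity of a TU is the fraction of samples at which it is
transcribed; population activity averages over replicate runs ("cells").
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ConfigurationError, TFState

# activity-class thresholds: high > 70%, medium 20-70%, low < 20%
HIGH_THRESHOLD = 0.7
LOW_THRESHOLD = 0.2


@dataclass(frozen=True)
class ActivityRecord:
    """Binary transcription time series of one run (sample x TU)."""

    tu_indices: np.ndarray
    samples: np.ndarray  # uint8 matrix, rows = sample instants
    sample_interval: float
    run_id: str = "run"
    seed: int = 0

    def __post_init__(self):
        s = np.asarray(self.samples)
        if s.ndim != 2 or s.shape[1] != len(self.tu_indices):
            raise ConfigurationError("samples must be (n_samples, n_TU)")
        if s.size and not np.isin(s, [0, 1]).all():
            raise ConfigurationError("samples must be binary")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    def mean_activity(self) -> np.ndarray:
        """Per-TU fraction of samples transcribed in this run."""
        if self.n_samples == 0:
            return np.full(len(self.tu_indices), np.nan)
        return self.samples.mean(axis=0)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"# run_id={self.run_id} seed={self.seed} "
                     f"sample_interval={self.sample_interval:g}\n")
            fh.write("sample_time\t" + "\t".join(
                f"TU{int(i)}" for i in self.tu_indices) + "\n")
            for k in range(self.n_samples):
                t = (k + 1) * self.sample_interval
                fh.write(f"{t:g}\t" + "\t".join(
                    str(int(v)) for v in self.samples[k]) + "\n")

    @classmethod
    def from_tsv(cls, path) -> "ActivityRecord":
        run_id, seed, interval = "run", 0, 100.0
        rows, tus = [], []
        with open(path) as fh:
            for line in fh:
                line = line.rstrip("\n")
                if line.startswith("#"):
                    for tok in line[1:].split():
                        k, _, v = tok.partition("=")
                        if k == "run_id":
                            run_id = v
                        elif k == "seed":
                            seed = int(v)
                        elif k == "sample_interval":
                            interval = float(v)
                elif line.startswith("sample_time"):
                    tus = [int(c[2:]) for c in line.split("\t")[1:]]
                elif line:
                    rows.append([int(v) for v in line.split("\t")[1:]])
        return cls(np.array(tus), np.array(rows, dtype=np.uint8).reshape(
            len(rows), len(tus)), interval, run_id, seed)


def detect_transcription(state, fibre, rc_transcribe: float = 1.8,
                         all_beads: bool = False) -> np.ndarray:
    """Binary transcription vector at one instant.

    Bit k is 1 iff at least one active-TF centre is within ``rc_transcribe``
    of recorded TU k (or of bead k, in whole-chromosome all-beads mode).
    """
    from . import _kernels

    pos = np.ascontiguousarray(state.positions, dtype=np.float64)
    m = fibre.n_beads
    if all_beads:
        tu_idx = np.arange(m, dtype=np.int64)
    else:
        tu_idx = fibre.tu_indices.astype(np.int64)
    tf_idx = m + np.flatnonzero(
        np.asarray(state.tf_states) == TFState.ACTIVE).astype(np.int64)
    out = np.zeros(tu_idx.shape[0], dtype=np.uint8)
    if tf_idx.size and tu_idx.size:
        _kernels._detect_bound(pos, tu_idx, tf_idx,
                               float(rc_transcribe) ** 2, out)
    return out


def classify_activity(activity: np.ndarray) -> np.ndarray:
    """'high' (>70%), 'medium' (20-70%), 'low' (<20%) labels."""
    activity = np.asarray(activity, dtype=float)
    labels = np.where(activity > HIGH_THRESHOLD, "high",
                      np.where(activity < LOW_THRESHOLD, "low", "medium"))
    return labels.astype(object)


def per_run_activity_matrix(records: list[ActivityRecord]) -> np.ndarray:
    """(run x TU) matrix of within-run mean activities (network samples)."""
    if not records:
        raise ConfigurationError("need at least one record")
    ref = records[0].tu_indices
    for r in records:
        if not np.array_equal(r.tu_indices, ref):
            raise ConfigurationError("records have mismatched TU sets")
    return np.vstack([r.mean_activity() for r in records])


def activity_profile(records: list[ActivityRecord]):
    """Population summary over runs.

    Returns (mean_activity, class_labels, per_run_matrix): the mean over all
    samples of all runs, its high/medium/low label, and the run x TU matrix
    of per-run activities used by the network inference.
    """
    per_run = per_run_activity_matrix(records)
    weights = np.array([r.n_samples for r in records], dtype=float)
    if weights.sum() == 0:
        raise ConfigurationError("records contain no samples")
    mean = np.average(per_run, axis=0, weights=weights)
    return mean, classify_activity(mean), per_run


@dataclass(frozen=True)
class BurstStats:
    """Per-TU burst and silent-gap durations (in tau_B)."""

    tu_indices: np.ndarray
    burst_durations: list  # list (per TU) of arrays of durations
    gap_durations: list

    def mean_burst_duration(self) -> np.ndarray:
        return np.array([float(np.mean(b)) if len(b) else np.nan
                         for b in self.burst_durations])


def _run_lengths(bits: np.ndarray):
    """(value, length) run-length encoding of a 0/1 series."""
    if bits.size == 0:
        return []
    change = np.flatnonzero(np.diff(bits)) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [bits.size]])
    return [(int(bits[s]), int(e - s)) for s, e in zip(starts, ends)]


def burst_statistics(record: ActivityRecord):
    """Bursts = maximal runs of consecutive transcribed samples.

    Returns (BurstStats, kymograph); the kymograph is the sample x TU matrix
    with TU columns ordered by position along the fibre.  Burst + gap
    durations for each TU always sum to the production time.
    """
    order = np.argsort(record.tu_indices)
    kymograph = record.samples[:, order]
    bursts, gaps = [], []
    for col in range(kymograph.shape[1]):
        bits = kymograph[:, col]
        b, g = [], []
        for value, length in _run_lengths(bits):
            (b if value == 1 else g).append(length * record.sample_interval)
        bursts.append(np.array(b))
        gaps.append(np.array(g))
    stats = BurstStats(record.tu_indices[order], bursts, gaps)
    return stats, kymograph


def tf_cluster_sizes(state, cluster_cutoff: float = 2.0) -> np.ndarray:
    """Multiset of active-TF cluster sizes (single-linkage, cutoff 2 sigma).

    Descriptive statistic for bridging-induced clustering; the cutoff is a
    reporting choice (adjacent spheres plus tolerance), not a dynamical one.
    """
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist

    tf_states = np.asarray(state.tf_states)
    n_tf = tf_states.shape[0]
    m = state.positions.shape[0] - n_tf
    active = np.flatnonzero(tf_states == TFState.ACTIVE)
    if active.size == 0:
        return np.array([], dtype=int)
    if active.size == 1:
        return np.array([1])
    pts = state.positions[m + active]
    z = linkage(pdist(pts), method="single")
    labels = fcluster(z, t=cluster_cutoff, criterion="distance")
    _, counts = np.unique(labels, return_counts=True)
    return np.sort(counts)[::-1]


def activity_summary_table(records: list[ActivityRecord], fibre=None):
    """Per-TU summary DataFrame: index, genomic bin if mapped, activity, class."""
    import pandas as pd

    mean, labels, _ = activity_profile(records)
    tus = records[0].tu_indices
    data = {"tu_index": tus, "activity": mean, "class": labels}
    if fibre is not None and fibre.genomic_map is not None:
        chrom, starts, ends = fibre.genomic_map
        data["chrom"] = chrom
        data["start"] = np.asarray(starts)[tus]
        data["end"] = np.asarray(ends)[tus]
    return pd.DataFrame(data)
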