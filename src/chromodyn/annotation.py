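"""Genomic annotation to bead classes, and simulation-vs-experiment comparison.

Whole-chromosome mode maps each 3 kbp bin of a chromosome to one bead.  In
the DHS model a bead is a TU if its bin overlaps a DNase-hypersensitive
site, euchromatin if it overlaps an H3K27ac peak, heterochromatin otherwise
(precedence DHS > H3K27ac; any overlap >= 1 bp counts).  The HMM model maps
the majority chromHMM state of the bin through a user-supplied state->class
table.  Comparison utilities rank simulated activity against an
experimental signal track (GRO-seq-like), build Hi-C-like contact maps from
trajectories, and fit the contact-probability decay exponent.

All interval handling is 0-based half-open (BED convention); 1-based
inclusive coordinates are converted at the parser boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .params import BeadClass, ConfigurationError

BIN_BP = 3000  # one bead = 3 kbp


# ---------------------------------------------------------------------------
# readers / writers (plain-text genomics formats)

def read_bed(path) -> pd.DataFrame:
    """BED3/BED4: chrom, start, end[, name]. Returns a sorted DataFrame."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"],
                     on_bad_lines="error") \
        if _n_columns(path) >= 4 else \
        pd.read_csv(path, sep="\t", header=None, comment="#",
                    names=["chrom", "start", "end"])
    if (df["end"] <= df["start"]).any():
        raise ConfigurationError(f"empty or inverted interval in {path}")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _n_columns(path) -> int:
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                return len(line.rstrip("\n").split("\t"))
    return 0


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start", "end", "value"])
    if (df["value"] < 0).any():
        raise ConfigurationError("signal track must be non-negative")
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def read_chrom_sizes(path) -> dict[str, int]:
    out = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split()[:2]
                out[chrom] = int(size)
    return out


def write_bed(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# bead classification

def n_bins(length: int) -> int:
    return int(math.ceil(length / BIN_BP))


def genomic_bins(chrom: str, length: int):
    """(chrom, starts, ends) tiling of the chromosome into 3 kbp bins
    (the last bin may be short)."""
    nb = n_bins(length)
    starts = np.arange(nb, dtype=np.int64) * BIN_BP
    ends = np.minimum(starts + BIN_BP, length)
    return chrom, starts, ends


def _mark_overlapping_bins(track: pd.DataFrame, chrom: str, length: int) -> np.ndarray:
    mask = np.zeros(n_bins(length), dtype=bool)
    sub = track[track["chrom"] == chrom]
    if len(sub) < len(track) and sub.empty and not track.empty:
        raise ConfigurationError(
            f"track has no intervals on {chrom}; assembly mismatch?")
    for start, end in zip(sub["start"].to_numpy(), sub["end"].to_numpy()):
        s = max(0, int(start))
        e = min(int(end), length)
        if e <= s:
            continue
        mask[s // BIN_BP: (e - 1) // BIN_BP + 1] = True
    return mask


def classify_beads_dhs(dhs_track: pd.DataFrame, h3k27ac_track: pd.DataFrame,
                       chrom: str, length: int) -> np.ndarray:
    """DHS model: DHS overlap -> TU; else H3K27ac overlap -> euchromatin;
    else heterochromatin.  Any overlap >= 1 bp counts."""
    dhs = _mark_overlapping_bins(dhs_track, chrom, length)
    ac = _mark_overlapping_bins(h3k27ac_track, chrom, length)
    classes = np.full(n_bins(length), BeadClass.HETEROCHROMATIN, dtype=np.int8)
    classes[ac] = BeadClass.EUCHROMATIN
    classes[dhs] = BeadClass.TU  # precedence: DHS wins over H3K27ac
    return classes


def classify_beads_hmm(chromhmm_track: pd.DataFrame,
                       state_map: dict[str, BeadClass | int],
                       chrom: str, length: int) -> np.ndarray:
    """HMM model: majority-overlap chromHMM state per bin, mapped to a class.

    Ties between states are broken in favour of the state contributed by the
    lower-coordinate interval.  Bins with no overlapping state are
    heterochromatin.  Unmapped state labels are an error.
    """
    nb = n_bins(length)
    sub = chromhmm_track[chromhmm_track["chrom"] == chrom]
    if "name" not in sub.columns:
        raise ConfigurationError("chromHMM track needs a state label in column 4")
    unknown = set(sub["name"]) - set(state_map)
    if unknown:
        raise ConfigurationError(
            f"chromHMM states missing from state_map: {sorted(unknown)}")
    overlap: list[dict] = [dict() for _ in range(nb)]
    first_start: list[dict] = [dict() for _ in range(nb)]
    for start, end, state in zip(sub["start"].to_numpy(),
                                 sub["end"].to_numpy(), sub["name"]):
        s = max(0, int(start))
        e = min(int(end), length)
        if e <= s:
            continue
        for b in range(s // BIN_BP, (e - 1) // BIN_BP + 1):
            ov = min(e, (b + 1) * BIN_BP) - max(s, b * BIN_BP)
            overlap[b][state] = overlap[b].get(state, 0) + ov
            first_start[b].setdefault(state, int(start))
    classes = np.full(nb, BeadClass.HETEROCHROMATIN, dtype=np.int8)
    for b in range(nb):
        if not overlap[b]:
            continue
        best = max(overlap[b].items(),
                   key=lambda kv: (kv[1], -first_start[b][kv[0]]))
        classes[b] = BeadClass(state_map[best[0]])
    return classes


def write_classification_tsv(classes: np.ndarray, chrom: str, length: int,
                             path) -> None:
    _, starts, ends = genomic_bins(chrom, length)
    names = {0: "TU", 1: "euchromatin", 2: "heterochromatin"}
    with open(path, "w") as fh:
        fh.write("bead_index\tchrom\tstart\tend\tclass\n")
        for i, (s, e) in enumerate(zip(starts, ends)):
            fh.write(f"{i}\t{chrom}\t{s}\t{e}\t{names[int(classes[i])]}\n")


# ---------------------------------------------------------------------------
# confinement sizing

def ellipsoid_for_territory(n_beads: int, volume_fraction: float = 0.14,
                            axis_ratios: tuple[float, float, float] = (2.0, 1.0, 1.0)
                            ) -> tuple[float, float, float]:
    """Semi-axes (in sigma) of the territory holding n_beads at the given
    bead volume fraction, with the given axis ratios (default prolate 2:1:1).

    Solves (4/3) pi a b c = n_beads (pi sigma^3 / 6) / phi.
    """
    if not (0 < volume_fraction < 0.5):
        raise ConfigurationError("volume fraction must be in (0, 0.5)")
    v_needed = n_beads * (math.pi / 6.0) / volume_fraction
    p, q, r = axis_ratios
    t = (v_needed / (4.0 / 3.0 * math.pi * p * q * r)) ** (1.0 / 3.0)
    axes = tuple(sorted((p * t, q * t, r * t), reverse=True))
    return axes


# ---------------------------------------------------------------------------
# simulation vs experiment comparison

def _patches(bead_classes: np.ndarray) -> list[np.ndarray]:
    """Maximal contiguous runs of beads that are all TU or all euchromatin."""
    cls = np.asarray(bead_classes)
    patches = []
    start = None
    for i in range(len(cls) + 1):
        binding = i < len(cls) and cls[i] in (BeadClass.TU, BeadClass.EUCHROMATIN)
        if binding and (start is None or cls[i] != cls[start]):
            if start is not None:
                patches.append(np.arange(start, i))
            start = i
        elif not binding and start is not None:
            patches.append(np.arange(start, i))
            start = None
    return patches


def rank_quintile_compare(sim_activity: np.ndarray, expt_signal: np.ndarray,
                          mode: str = "all",
                          bead_classes: np.ndarray | None = None):
    """Quintile heat-map counts and Spearman correlation of two rankings.

    Both vectors are mid-ranked (ties averaged) and binned into quintiles;
    the 5x5 joint-count matrix is the published heat-map representation, and
    the Spearman correlation is computed on the unbinned ranks.  Modes:
    ``all`` beads, ``tu_only``, or ``patch`` (vectors averaged within
    contiguous all-TU / all-euchromatin patches before ranking).
    """
    sim = np.asarray(sim_activity, dtype=float)
    expt = np.asarray(expt_signal, dtype=float)
    if sim.shape != expt.shape:
        raise ConfigurationError("activity and signal vectors differ in length")
    if mode == "tu_only":
        if bead_classes is None:
            raise ConfigurationError("tu_only mode needs bead classes")
        keep = np.asarray(bead_classes) == BeadClass.TU
        sim, expt = sim[keep], expt[keep]
    elif mode == "patch":
        if bead_classes is None:
            raise ConfigurationError("patch mode needs bead classes")
        patches = _patches(bead_classes)
        sim = np.array([sim[p].mean() for p in patches])
        expt = np.array([expt[p].mean() for p in patches])
    elif mode != "all":
        raise ConfigurationError(f"unknown mode {mode!r}")
    n = sim.size
    if n < 3:
        raise ConfigurationError("need at least 3 observations")
    r_sim = stats.rankdata(sim)  # mid-ranks for ties
    r_expt = stats.rankdata(expt)
    q_sim = np.minimum((5 * (r_sim - 0.5) / n).astype(int), 4)
    q_expt = np.minimum((5 * (r_expt - 0.5) / n).astype(int), 4)
    heat = np.zeros((5, 5), dtype=np.int64)
    np.add.at(heat, (q_expt, q_sim), 1)
    rho, p = stats.spearmanr(sim, expt)
    return heat, float(rho), float(p)


def nearest_tu_distance_correlation(activity: np.ndarray,
                                    tu_positions: np.ndarray):
    """Spearman correlation of TU activity with 1D distance (in beads) to
    the nearest other TU.  Returns (r, p); (nan, nan) when degenerate."""
    act = np.asarray(activity, dtype=float)
    pos = np.sort(np.asarray(tu_positions, dtype=np.int64))
    if pos.size < 3:
        raise ConfigurationError("need at least 3 TUs")
    order = np.argsort(np.asarray(tu_positions))
    act = act[order]
    dist = np.empty(pos.size, dtype=float)
    for k in range(pos.size):
        others = np.abs(np.delete(pos, k) - pos[k])
        dist[k] = others.min()
    if np.std(dist) == 0 or np.std(act) == 0:
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(act, dist)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# contact maps

@dataclass(frozen=True)
class ContactMap:
    """Symmetric contact counts between genomic bins (default 30 kbp)."""

    bin_width_bp: int
    counts: np.ndarray
    tu_bin_mask: np.ndarray | None = None

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]


def contact_map_from_trajectories(trajectories, n_beads: int,
                                  contact_cutoff: float = 3.5,
                                  bin_width_bp: int = 30_000,
                                  tu_mask_beads: np.ndarray | None = None
                                  ) -> ContactMap:
    """Hi-C-like contact map accumulated over trajectory frames.

    A bead pair is in contact iff centre distance <= contact_cutoff (3.5
    sigma by default; exposed because capture criteria vary).  Counts are
    pooled into bins of bin_width_bp (10 beads at 3 kbp/bead).  When
    ``tu_mask_beads`` is given, only pairs whose bins both contain a TU are
    counted (promoter-capture-like restriction is applied downstream via
    ``tu_bin_mask``).
    """
    from . import _kernels

    beads_per_bin = bin_width_bp // BIN_BP
    nb = int(math.ceil(n_beads / beads_per_bin))
    counts = np.zeros((nb, nb), dtype=np.int64)
    pair_i, pair_j = _kernels.alloc_pair_arrays(n_beads, 256)
    n_frames = 0
    for frames in trajectories:
        for frame in frames:
            pos = np.ascontiguousarray(frame[1][:n_beads], dtype=np.float64)
            npairs = _kernels._pairs_within(pos, float(contact_cutoff),
                                            pair_i, pair_j)
            if npairs < 0:
                raise MemoryError("contact pair capacity exceeded")
            bi = pair_i[:npairs] // beads_per_bin
            bj = pair_j[:npairs] // beads_per_bin
            np.add.at(counts, (bi, bj), 1)
            np.add.at(counts, (bj, bi), 1)
            n_frames += 1
    if n_frames == 0:
        raise ConfigurationError("no trajectory frames supplied")
    tu_bin_mask = None
    if tu_mask_beads is not None:
        tu_bin_mask = np.zeros(nb, dtype=bool)
        tu_bin_mask[np.asarray(tu_mask_beads) // beads_per_bin] = True
    return ContactMap(bin_width_bp, counts, tu_bin_mask)


def contact_decay_exponent(cmap: ContactMap, s_min: int = 30_000,
                           s_max: int = 1_500_000) -> float:
    """Least-squares slope of log P(s) vs log s over [s_min, s_max].

    P(s) is the mean contact count over bin pairs at genomic separation s.
    """
    nb = cmap.n_bins
    d_min = max(1, int(round(s_min / cmap.bin_width_bp)))
    d_max = min(nb - 1, int(round(s_max / cmap.bin_width_bp)))
    if d_max <= d_min:
        raise ConfigurationError("contact map does not cover the fit range")
    seps, means = [], []
    for d in range(d_min, d_max + 1):
        diag = np.diagonal(cmap.counts, offset=d)
        if cmap.tu_bin_mask is not None:
            keep = cmap.tu_bin_mask[:nb - d] & cmap.tu_bin_mask[d:]
            diag = diag[keep]
        if diag.size and diag.mean() > 0:
            seps.append(d * cmap.bin_width_bp)
            means.append(diag.mean())
    if len(seps) < 3:
        raise ConfigurationError("insufficient non-empty diagonals in fit range")
    slope, _ = np.polyfit(np.log(seps), np.log(means), 1)
    return float(slope)


def write_contact_map(cmap: ContactMap, path_triplets, path_dense=None) -> None:
    """Sparse triplet text (bin_i, bin_j, count) and optional dense matrix."""
    with open(path_triplets, "w") as fh:
        fh.write("bin_i\tbin_j\tcount\n")
        ii, jj = np.nonzero(np.triu(cmap.counts))
        for i, j in zip(ii, jj):
            fh.write(f"{i}\t{j}\t{cmap.counts[i, j]}\n")
    if path_dense:
        np.savetxt(path_dense, cmap.counts, fmt="%d", delimiter="\t")


# ---------------------------------------------------------------------------
# synthetic annotation fixtures (test stand-ins for DHS/ChIP/GRO-seq files)

@dataclass(frozen=True)
class SyntheticAnnotation:
    """Synthetic annotation tracks with known ground truth (test fixture)."""

    chrom: str
    length: int
    classes: np.ndarray        # ground-truth bead classes
    activity: np.ndarray       # per-bead reference activity
    signal: np.ndarray         # per-bead signal (rank-correlated to activity)
    dhs: pd.DataFrame
    h3k27ac: pd.DataFrame
    signal_track: pd.DataFrame
    super_enhancers: pd.DataFrame

    def write(self, out_dir) -> dict:
        import os

        paths = {}
        for name, df in (("dhs.bed", self.dhs), ("h3k27ac.bed", self.h3k27ac),
                         ("signal.bedgraph", self.signal_track),
                         ("super_enhancers.bed", self.super_enhancers)):
            p = os.path.join(out_dir, name)
            df.to_csv(p, sep="\t", header=False, index=False)
            paths[name] = p
        return paths


def spearman_to_pearson(rho_s: float) -> float:
    """Gaussian-copula conversion: rho = 2 sin(pi rho_s / 6)."""
    return 2.0 * math.sin(math.pi * rho_s / 6.0)


def synthetic_annotation_fixture(chrom_length: int, tu_density: float = 0.039,
                                 patchiness: float = 4.0,
                                 target_rank_corr: float = 0.4,
                                 seed: int = 0,
                                 activity: np.ndarray | None = None,
                                 chrom: str = "chrSyn") -> SyntheticAnnotation:
    """Clustered synthetic DHS/H3K27ac/GRO-seq-like tracks with known truth.

    Bead classes follow a 3-state Markov chain whose stationary density of
    TUs is ``tu_density`` and whose mean patch length is ``patchiness``
    beads (euchromatin fraction fixed at 4x the TU fraction, the remainder
    heterochromatin).  The signal track is built through a Gaussian copula
    so its Spearman correlation with the reference activity equals
    ``target_rank_corr``.
    """
    if not (0 < tu_density < 0.2) or patchiness < 1:
        raise ConfigurationError("infeasible fixture parameters")
    rng = np.random.default_rng(seed)
    nb = n_bins(chrom_length)
    pi = np.array([tu_density, min(4.0 * tu_density, 0.8), 0.0])
    pi[2] = 1.0 - pi[0] - pi[1]
    if pi[2] <= 0:
        raise ConfigurationError("tu_density too high for the class mixture")
    # sticky resampling chain: keep the previous class with prob 1 - 1/L,
    # otherwise redraw from pi -- the stationary law is exactly pi and the
    # mean patch length is ~patchiness
    leave = 1.0 / patchiness
    redraw = rng.random(nb) < leave
    fresh = rng.choice(3, size=nb, p=pi).astype(np.int8)
    classes = np.empty(nb, dtype=np.int8)
    classes[0] = fresh[0]
    for i in range(1, nb):
        classes[i] = fresh[i] if redraw[i] else classes[i - 1]
    # interval tracks from the classes
    _, starts, ends = genomic_bins(chrom, chrom_length)
    dhs_rows, ac_rows = [], []
    for i in range(nb):
        if classes[i] == BeadClass.TU:
            mid = (starts[i] + ends[i]) // 2
            dhs_rows.append((chrom, mid - 100, mid + 100, f"dhs{i}"))
        elif classes[i] == BeadClass.EUCHROMATIN:
            ac_rows.append((chrom, starts[i], ends[i], f"ac{i}"))
    dhs = pd.DataFrame(dhs_rows, columns=["chrom", "start", "end", "name"])
    ac = pd.DataFrame(_merge_adjacent(ac_rows),
                      columns=["chrom", "start", "end", "name"])
    # reference activity: binding beads active, modulated by local TU density
    if activity is None:
        # continuous positive reference activity (no ties, so the copula
        # coupling below is not attenuated): class-dependent baseline times
        # a local-TU-density boost and lognormal cell-to-cell noise
        base = np.where(classes == BeadClass.TU, 0.6,
                        np.where(classes == BeadClass.EUCHROMATIN, 0.2, 0.02))
        kernel = np.ones(11) / 11.0
        local = np.convolve((classes == BeadClass.TU).astype(float), kernel,
                            mode="same")
        activity = base * (1.0 + 2.0 * local) * np.exp(
            rng.normal(0.0, 0.25, nb))
    activity = np.asarray(activity, dtype=float)
    # copula-coupled signal
    # couple the signal to the activity through a Gaussian copula: draw an
    # i.i.d. bivariate-normal sample with the matching Pearson rho and give
    # the bead holding the k-th smallest activity the y-value of the draw
    # with the k-th smallest x -- the joint rank law is then exactly that of
    # the copula, so the recovered Spearman is unbiased
    rho = spearman_to_pearson(target_rank_corr)
    noise_coef = math.sqrt(max(1.0 - rho * rho, 0.0))
    if noise_coef < 1e-7:  # |rho| = 1 up to float error: exact comonotonicity
        noise_coef = 0.0
        rho = math.copysign(1.0, rho)
    x = rng.normal(size=nb)
    y = rho * x + noise_coef * rng.normal(size=nb)
    signal = np.empty(nb)
    signal[np.argsort(activity, kind="stable")] = np.exp(y[np.argsort(x)])
    sig_df = pd.DataFrame({"chrom": chrom, "start": starts, "end": ends,
                           "value": np.round(signal, 6)})
    # super-enhancers: the strongest contiguous euchromatic stretches
    se_rows = []
    for p in _patches(classes):
        if classes[p[0]] == BeadClass.EUCHROMATIN and len(p) >= 3:
            se_rows.append((signal[p].mean(), p))
    se_rows.sort(key=lambda t: -t[0])
    se = pd.DataFrame(
        [(chrom, int(starts[p[0]]), int(ends[p[-1]]), f"SE{q}")
         for q, (_, p) in enumerate(se_rows[:max(1, len(se_rows) // 10)])],
        columns=["chrom", "start", "end", "name"])
    return SyntheticAnnotation(chrom, chrom_length, classes, activity, signal,
                               dhs, ac, sig_df, se)


def _merge_adjacent(rows):
    merged = []
    for chrom, s, e, name in rows:
        if merged and merged[-1][1] <= s <= merged[-1][2]:
            merged[-1][2] = max(merged[-1][2], e)
        else:
            merged.append([chrom, s, e, name])
    return [tuple(m) for m in merged]
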