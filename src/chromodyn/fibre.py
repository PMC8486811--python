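"""Chromatin fibre construction and editing.

A :class:`ChromatinFibre` is the static topology of one simulation: per-bead
binding classes, backbone bonds (FENE, or harmonic on looped chains), bending
triplets, permanent loop bonds, and an optional genomic map (3 kbp bins).
All in-silico perturbations -- knockouts, heterochromatin islands, loop sets,
deletions -- are pure functions returning an edited copy.

Bead classes are the single source of truth for binding behaviour; the list
of TUs recorded by the transcription machinery is a derived view, except
after a knockout, where the abrogated bead keeps its reporting identity
(its activity is still recorded and is ~0).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np

from .params import (
    BeadClass,
    Confinement,
    ConfigurationError,
    InteractionParams,
)

#: Frozen seed of the repository's reference 1000-bead toy fibre.  The random
#: TU placement it induces is representative of any arbitrary positioning;
#: this particular draw is pinned because it places TUs at beads 905, 907,
#: 930 and 931, so the published mutant coordinates (knockout of bead 930,
#: heterochromatin island over beads 901-940) apply verbatim.
REFERENCE_SEED = 361223


@dataclass(frozen=True)
class BondSpec:
    i: int
    j: int
    kind: str  # fene | harmonic_backbone | harmonic_loop

    def __post_init__(self):
        if self.i == self.j:
            raise ConfigurationError("bond endpoints must differ")
        if self.kind not in ("fene", "harmonic_backbone", "harmonic_loop"):
            raise ConfigurationError(f"unknown bond kind {self.kind!r}")


@dataclass(frozen=True)
class AngleSpec:
    i: int
    j: int
    k: int

    def __post_init__(self):
        if not (self.j == self.i + 1 and self.k == self.i + 2):
            raise ConfigurationError("angle triplets must be consecutive beads")


@dataclass(frozen=True)
class ChromatinFibre:
    n_beads: int
    bead_class: np.ndarray            # int8, BeadClass values
    bonds: tuple[BondSpec, ...]
    angles: tuple[AngleSpec, ...]
    loops: tuple[tuple[int, int], ...] = ()
    genomic_map: tuple | None = None  # (chrom: str, starts: array, ends: array)
    recorded_tus: np.ndarray | None = None  # pinned reporting list (knockouts)

    @property
    def tu_indices(self) -> np.ndarray:
        """Beads whose transcription is recorded (derived from class unless pinned)."""
        if self.recorded_tus is not None:
            return np.asarray(self.recorded_tus, dtype=np.int64)
        return np.flatnonzero(np.asarray(self.bead_class) == BeadClass.TU)

    def __post_init__(self):
        object.__setattr__(self, "bead_class",
                           np.asarray(self.bead_class, dtype=np.int8))


def validate_fibre(fibre: ChromatinFibre) -> None:
    """Single validator run after every edit: connectivity, ranges, classes."""
    m = fibre.n_beads
    if fibre.bead_class.shape != (m,):
        raise ConfigurationError("bead_class length != n_beads")
    if not np.isin(fibre.bead_class, [0, 1, 2]).all():
        raise ConfigurationError("invalid bead class label")
    backbone = sorted((min(b.i, b.j), max(b.i, b.j))
                      for b in fibre.bonds if b.kind != "harmonic_loop")
    expected = [(i, i + 1) for i in range(m - 1)]
    if backbone != expected:
        raise ConfigurationError("backbone bonds must connect consecutive beads")
    kinds = {b.kind for b in fibre.bonds if b.kind != "harmonic_loop"}
    if len(kinds) > 1:
        raise ConfigurationError("mixed backbone bond kinds")
    loop_bonds = sorted((min(b.i, b.j), max(b.i, b.j))
                        for b in fibre.bonds if b.kind == "harmonic_loop")
    if loop_bonds != sorted((min(i, j), max(i, j)) for i, j in fibre.loops):
        raise ConfigurationError("loop bond list inconsistent with loop anchors")
    for i, j in fibre.loops:
        if not (0 <= i < m and 0 <= j < m) or abs(i - j) < 2:
            raise ConfigurationError(f"invalid loop anchors ({i}, {j})")
        if (min(i, j), max(i, j)) in set(expected):
            raise ConfigurationError("loop bond duplicates a backbone bond")
    for a in fibre.angles:
        if a.k >= m or a.i < 0:
            raise ConfigurationError("angle indices out of range")
    if fibre.genomic_map is not None:
        _, starts, ends = fibre.genomic_map
        if len(starts) != m or len(ends) != m:
            raise ConfigurationError("genomic map length != n_beads")
        if not (np.asarray(ends) > np.asarray(starts)).all():
            raise ConfigurationError("genomic map intervals must be non-empty")


def _chain_bonds(m: int, kind: str) -> tuple[BondSpec, ...]:
    return tuple(BondSpec(i, i + 1, kind) for i in range(m - 1))


def _chain_angles(m: int) -> tuple[AngleSpec, ...]:
    return tuple(AngleSpec(i, i + 1, i + 2) for i in range(m - 2))


def build_toy_fibre(M: int = 1000, n_tu: int = 39,
                    seed: int = REFERENCE_SEED) -> ChromatinFibre:
    """Toy chain: M beads, n_tu TUs placed uniformly at random, rest euchromatin.

    39 TUs per 1000 beads (3 Mbp) matches the TU linear density of human
    chromosome 22 (~13 TUs/Mbp).
    """
    if n_tu >= M:
        raise ConfigurationError("n_tu must be smaller than the chain length")
    rng = np.random.default_rng(seed)
    classes = np.full(M, BeadClass.EUCHROMATIN, dtype=np.int8)
    tus = rng.choice(M, size=n_tu, replace=False)
    classes[tus] = BeadClass.TU
    fib = ChromatinFibre(M, classes, _chain_bonds(M, "fene"), _chain_angles(M))
    validate_fibre(fib)
    return fib


def build_uniform_fibre(M: int, bead_class=BeadClass.EUCHROMATIN) -> ChromatinFibre:
    """Homogeneous chain (used for phantom-chain and annotation tests)."""
    classes = np.full(M, bead_class, dtype=np.int8)
    fib = ChromatinFibre(M, classes, _chain_bonds(M, "fene"), _chain_angles(M))
    validate_fibre(fib)
    return fib


def fibre_from_classes(classes: np.ndarray,
                       genomic_map=None) -> ChromatinFibre:
    """Chain from an explicit per-bead class vector (annotation-driven mode)."""
    classes = np.asarray(classes, dtype=np.int8)
    m = classes.shape[0]
    fib = ChromatinFibre(m, classes, _chain_bonds(m, "fene"), _chain_angles(m),
                         genomic_map=genomic_map)
    validate_fibre(fib)
    return fib


def add_loops(fibre: ChromatinFibre,
              loop_anchor_pairs: list[tuple[int, int]]) -> ChromatinFibre:
    """Add permanent harmonic loop bonds (Rbar = 1.8 sigma).

    On looped chains every backbone bond is converted from FENE to harmonic
    (Rbar = 1.1 sigma) for numerical stability, matching the published
    looped-chain parameterisation.  An empty anchor list is a no-op.
    """
    if not loop_anchor_pairs:
        return fibre
    anchors = [(min(i, j), max(i, j)) for i, j in loop_anchor_pairs]
    for i, j in anchors:
        if not (0 <= i < fibre.n_beads and 0 <= j < fibre.n_beads):
            raise ConfigurationError(f"loop anchor out of range: ({i}, {j})")
    new_backbone = _chain_bonds(fibre.n_beads, "harmonic_backbone")
    loop_bonds = tuple(BondSpec(i, j, "harmonic_loop") for i, j in anchors)
    out = replace(fibre, bonds=new_backbone + loop_bonds,
                  loops=fibre.loops + tuple(anchors))
    validate_fibre(out)
    return out


def set_region_class(fibre: ChromatinFibre, start: int, end: int,
                     bead_class) -> ChromatinFibre:
    """Relabel beads in [start, end) -- heterochromatin islands, euchromatin embedment."""
    if not (0 <= start < end <= fibre.n_beads):
        raise ConfigurationError(f"invalid region [{start}, {end})")
    classes = fibre.bead_class.copy()
    classes[start:end] = BeadClass(bead_class)
    recorded = fibre.recorded_tus
    if recorded is not None and BeadClass(bead_class) != BeadClass.TU:
        recorded = recorded[(recorded < start) | (recorded >= end)]
    out = replace(fibre, bead_class=classes, recorded_tus=recorded)
    validate_fibre(out)
    return out


def knockout_tu(fibre: ChromatinFibre, tu_index: int) -> ChromatinFibre:
    """Abrogate TF binding at one TU (SNP/eQTL model).

    The bead becomes non-binding (heterochromatin-like) but keeps its place
    in the recorded TU list, so its (near-zero) activity is still reported.
    Idempotent.
    """
    recorded = fibre.tu_indices
    if tu_index not in recorded:
        raise ConfigurationError(f"bead {tu_index} is not a recorded TU")
    classes = fibre.bead_class.copy()
    classes[tu_index] = BeadClass.HETEROCHROMATIN
    out = replace(fibre, bead_class=classes, recorded_tus=recorded)
    validate_fibre(out)
    return out


def delete_region(fibre: ChromatinFibre, start_bead: int,
                  end_bead: int) -> ChromatinFibre:
    """Remove beads start_bead..end_bead (inclusive) and re-join the chain.

    The junction bond uses the same kind as the rest of the backbone; bond,
    angle and loop lists are re-indexed; the genomic map of surviving beads
    is preserved (so positions stay in wild-type coordinates).  Deleting an
    empty range is the identity.
    """
    if start_bead > end_bead:
        return fibre
    if not (0 <= start_bead and end_bead < fibre.n_beads):
        raise ConfigurationError("deletion range out of bounds")
    n_del = end_bead - start_bead + 1
    if n_del >= fibre.n_beads:
        raise ConfigurationError("cannot delete the whole chain")
    keep = np.ones(fibre.n_beads, dtype=bool)
    keep[start_bead:end_bead + 1] = False
    new_index = np.cumsum(keep) - 1  # old -> new
    m = fibre.n_beads - n_del
    classes = fibre.bead_class[keep]
    kind = next((b.kind for b in fibre.bonds if b.kind != "harmonic_loop"), "fene")
    loops = tuple((int(new_index[i]), int(new_index[j])) for i, j in fibre.loops
                  if keep[i] and keep[j])
    bonds = _chain_bonds(m, kind) + tuple(
        BondSpec(i, j, "harmonic_loop") for i, j in loops)
    gmap = None
    if fibre.genomic_map is not None:
        chrom, starts, ends = fibre.genomic_map
        gmap = (chrom, np.asarray(starts)[keep], np.asarray(ends)[keep])
    recorded = fibre.recorded_tus
    if recorded is not None:
        recorded = new_index[recorded[keep[recorded]]]
    out = ChromatinFibre(m, classes, bonds, _chain_angles(m), loops,
                         gmap, recorded)
    validate_fibre(out)
    return out


# ---------------------------------------------------------------------------
# initial conformations


def initial_conformation(fibre: ChromatinFibre, confinement: Confinement,
                         seed: int, n_tf: int = 0,
                         params: InteractionParams | None = None,
                         bond_length: float = 1.1,
                         max_retries: int = 200) -> np.ndarray:
    """Self-avoiding-biased random-walk conformation plus uniformly placed TFs.

    The walk keeps successive beads ``bond_length`` apart (safely below the
    FENE maximum R0 = 1.6 sigma), avoids the most recent beads, and stays
    inside the shrunken confinement.  Residual overlaps are removed by the
    capped-force push-off at the start of every run.
    """
    params = params or InteractionParams()
    rng = np.random.default_rng(seed)
    m = fibre.n_beads
    pos = np.empty((m + n_tf, 3))
    margin = params.rc_rep

    def inside(p):
        if confinement.kind == "none":
            return True
        a, b, c = confinement.semi_axes
        return ((p[0] / (a - margin)) ** 2 + (p[1] / (b - margin)) ** 2
                + (p[2] / (c - margin)) ** 2) < 1.0

    pos[0] = 0.0
    recent = 12  # local self-avoidance window
    for i in range(1, m):
        for attempt in range(max_retries):
            v = rng.normal(size=3)
            v *= bond_length / np.linalg.norm(v)
            cand = pos[i - 1] + v
            if not inside(cand):
                continue
            lo = max(0, i - recent)
            d2 = np.sum((pos[lo:i - 1] - cand) ** 2, axis=1)
            if d2.size and d2.min() < 0.64:  # 0.8 sigma
                continue
            pos[i] = cand
            break
        else:
            raise ConfigurationError(
                f"could not place bead {i} inside the confinement")
    # TFs uniform in the accessible volume
    if confinement.kind == "none":
        lo, hi = pos[:m].min(axis=0) - 2.0, pos[:m].max(axis=0) + 2.0
    else:
        a, b, c = confinement.semi_axes
        lo = -np.array([a, b, c]) + margin
        hi = -lo
    for t in range(n_tf):
        for attempt in range(max_retries):
            cand = rng.uniform(lo, hi)
            if inside(cand):
                pos[m + t] = cand
                break
        else:
            raise ConfigurationError("could not place a TF inside the confinement")
    return pos


# ---------------------------------------------------------------------------
# serialisation

_CLASS_NAMES = {0: "TU", 1: "euchromatin", 2: "heterochromatin"}
_CLASS_CODES = {v: k for k, v in _CLASS_NAMES.items()}


def fibre_to_text(fibre: ChromatinFibre) -> str:
    """Tabular text serialisation: beads section, then bonds, then loops."""
    buf = io.StringIO()
    buf.write("#beads\tindex\tclass\tchrom\tstart\tend\trecorded\n")
    recorded = set(fibre.tu_indices.tolist())
    for i in range(fibre.n_beads):
        if fibre.genomic_map is not None:
            chrom, starts, ends = fibre.genomic_map
            loc = f"{chrom}\t{int(starts[i])}\t{int(ends[i])}"
        else:
            loc = ".\t.\t."
        buf.write(f"bead\t{i}\t{_CLASS_NAMES[int(fibre.bead_class[i])]}\t{loc}"
                  f"\t{1 if i in recorded else 0}\n")
    buf.write("#bonds\ti\tj\tkind\n")
    for b in fibre.bonds:
        buf.write(f"bond\t{b.i}\t{b.j}\t{b.kind}\n")
    buf.write("#loops\ti\tj\n")
    for i, j in fibre.loops:
        buf.write(f"loop\t{i}\t{j}\n")
    return buf.getvalue()


def fibre_from_text(text: str) -> ChromatinFibre:
    classes, bonds, loops = [], [], []
    chroms, starts, ends, recorded = [], [], [], []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "bead":
            classes.append(_CLASS_CODES[parts[2]])
            chroms.append(parts[3])
            starts.append(parts[4])
            ends.append(parts[5])
            if int(parts[6]):
                recorded.append(int(parts[1]))
        elif parts[0] == "bond":
            bonds.append(BondSpec(int(parts[1]), int(parts[2]), parts[3]))
        elif parts[0] == "loop":
            loops.append((int(parts[1]), int(parts[2])))
    m = len(classes)
    gmap = None
    if chroms and chroms[0] != ".":
        gmap = (chroms[0], np.array([int(s) for s in starts]),
                np.array([int(e) for e in ends]))
    classes = np.asarray(classes, dtype=np.int8)
    rec = np.asarray(sorted(recorded), dtype=np.int64)
    derived = np.flatnonzero(classes == BeadClass.TU)
    pinned = None if np.array_equal(rec, derived) else rec
    fib = ChromatinFibre(m, classes, tuple(bonds), _chain_angles(m),
                         tuple(loops), gmap, pinned)
    validate_fibre(fib)
    return fib


# ---------------------------------------------------------------------------
# presets

def reference_toy_fibre() -> ChromatinFibre:
    """The frozen 1000-bead, 39-TU reference fibre (seed pinned)."""
    return build_toy_fibre(1000, 39, REFERENCE_SEED)


def reference_loop_anchors(fibre: ChromatinFibre | None = None,
                           n_loops: int = 8) -> list[tuple[int, int]]:
    """Eight permanent, non-overlapping loops of 40-100 beads.

    Chosen deterministically to cover TU-dense stretches of the reference
    fibre: candidate windows of alternating sizes are ranked by TU content
    and picked greedily without overlap.
    """
    fibre = fibre or reference_toy_fibre()
    is_tu = np.asarray(fibre.bead_class) == BeadClass.TU
    sizes = [100, 40, 80, 60, 100, 40, 80, 60]
    chosen: list[tuple[int, int]] = []
    occupied = np.zeros(fibre.n_beads, dtype=bool)
    for size in sizes[:n_loops]:
        best, best_count = None, -1
        for start in range(0, fibre.n_beads - size):
            if occupied[start:start + size + 1].any():
                continue
            count = int(is_tu[start:start + size + 1].sum())
            if count > best_count:
                best, best_count = start, count
        if best is None:
            break
        chosen.append((best, best + size))
        occupied[best:best + size + 1] = True
    return sorted(chosen)


def all_loops_anchors(n_beads: int, loop_size: int = 50) -> list[tuple[int, int]]:
    """Consecutive non-overlapping loops tiling the whole chain."""
    anchors = []
    for start in range(0, n_beads - loop_size + 1, loop_size):
        anchors.append((start, start + loop_size - 1))
    return anchors


def preset_fibre(name: str) -> ChromatinFibre:
    """Named fibres addressable from the CLI.

    ``toy-wt`` | ``toy-loops`` | ``toy-allloops`` | ``toy-het-island`` |
    ``toy-eu-island`` | ``toy-ko-<bead>``
    """
    wt = reference_toy_fibre()
    if name == "toy-wt":
        return wt
    if name == "toy-loops":
        return add_loops(wt, reference_loop_anchors(wt))
    if name == "toy-allloops":
        return add_loops(wt, all_loops_anchors(wt.n_beads))
    if name == "toy-het-island":
        # the embedded TUs keep their reporting identity so their (silenced)
        # activity can be compared against the wild type
        fib = set_region_class(wt, 901, 941, BeadClass.HETEROCHROMATIN)
        return replace(fib, recorded_tus=wt.tu_indices)
    if name == "toy-eu-island":
        fib = set_region_class(wt, 901, 941, BeadClass.EUCHROMATIN)
        return replace(fib, recorded_tus=wt.tu_indices)
    if name.startswith("toy-ko-"):
        return knockout_tu(wt, int(name.rsplit("-", 1)[1]))
    raise ConfigurationError(f"unknown fibre preset {name!r}")
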