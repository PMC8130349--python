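"""Synthetic permafrost metagenome generator with ancient-DNA taphonomy.

Simulates the fate of microbial genomes frozen in sediment: post-mortem
fragmentation, cytosine deamination concentrated at fragment termini,
blocking lesions (abasic sites, dimers) and nicks, partitioning into
intracellular (iDNA) and extracellular (eDNA) extraction fractions, optional
in-vitro enzymatic repair, and sequencing into a 2x2 library design
(iDNA/eDNA x repaired/unrepaired) with complete per-read ground truth.

The deamination law is the overhang-decay model standard in ancient-DNA
phenomenology: a C site at 0-based 5'-offset p deaminates with probability

    P(p) = delta_ds + (delta_ss - delta_ds) * q**p

and symmetrically, deamination on the complementary strand near the 3' end
produces G->A-generating lesions with the mirrored offset.  Living
populations are constructed with ~zero lesion rates and >10 kb median
fragments; fossil populations with short (~100-300 bp) fragments and high
terminal deamination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._rng import child_rng

__all__ = [
    "DamageParams",
    "PopulationSpec",
    "LibrarySpec",
    "Lesion",
    "Fragment",
    "SimRead",
    "SequencedLibrary",
    "generate_reference_genomes",
    "simulate_taphonomy",
    "partition_idna_edna",
    "apply_repair",
    "conversion_probability",
    "sequence_library",
    "living_damage",
    "fossil_damage",
]

VITALITIES = ("living", "dead_intact", "lysed")

#: lesion kinds that block library conversion (polymerase stops / no ligation)
BLOCKING_KINDS = frozenset({"abasic", "nick", "blocker"})

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTN", b"TGCAN"):
    _COMP[_a] = _b
_BASE_INDEX = np.full(256, 255, dtype=np.uint8)
for _i, _a in enumerate(b"ACGT"):
    _BASE_INDEX[_a] = _i

#: default per-vitality probability of a fragment leaking to the "wrong" pool
DEFAULT_LEAKAGE = {"living": 0.05, "dead_intact": 0.1, "lysed": 0.05}


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class DamageParams:
    """Lesion-process parameters for one population.

    delta_ss / delta_ds: per-site deamination probability in single-stranded
    overhangs vs. interior duplex DNA; q: geometric persistence of the
    overhang effect with distance from the terminus; nick_rate and
    blocker_rate are Poisson intensities per bp; frag_mu / frag_sigma are the
    log-scale parameters of the lognormal fragment-length distribution.
    """

    delta_ss: float = 0.0
    delta_ds: float = 0.0
    q: float = 0.6
    nick_rate: float = 0.0
    blocker_rate: float = 0.0
    frag_mu: float = math.log(200.0)
    frag_sigma: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta_ds <= self.delta_ss <= 1.0):
            raise ValueError("require 0 <= delta_ds <= delta_ss <= 1")
        if not (0.0 <= self.q < 1.0):
            raise ValueError("q must be in [0, 1)")
        if self.nick_rate < 0 or self.blocker_rate < 0:
            raise ValueError("lesion rates must be >= 0")
        if math.exp(self.frag_mu + 0.5 * self.frag_sigma**2) < 30:
            raise ValueError("expected fragment length must be >= 30 bp")


def living_damage(frag_mu: float = math.log(15_000.0),
                  frag_sigma: float = 0.35) -> DamageParams:
    """Damage parameters for a living population: intact, high-MW DNA."""
    return DamageParams(delta_ss=0.0, delta_ds=0.0, q=0.6,
                        nick_rate=0.0, blocker_rate=0.0,
                        frag_mu=frag_mu, frag_sigma=frag_sigma)


def fossil_damage(delta_ss: float = 0.3, delta_ds: float = 0.01,
                  q: float = 0.6, nick_rate: float = 0.001,
                  blocker_rate: float = 0.002,
                  frag_mu: float = math.log(200.0),
                  frag_sigma: float = 0.5) -> DamageParams:
    """Damage parameters for an old-stratum (fossil) population."""
    return DamageParams(delta_ss=delta_ss, delta_ds=delta_ds, q=q,
                        nick_rate=nick_rate, blocker_rate=blocker_rate,
                        frag_mu=frag_mu, frag_sigma=frag_sigma)


@dataclass(frozen=True)
class PopulationSpec:
    """Ground truth for one simulated genome population."""

    genome_id: str
    genome_length: int
    gc_fraction: float
    relative_abundance: float = 1.0
    vitality: str = "living"
    damage: DamageParams = field(default_factory=living_damage)
    ptr: float = 1.0  # peak-to-trough replication ratio (>= 1)
    ori_position: int = 0
    ter_position: int | None = None  # default: opposite the origin

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.relative_abundance < 0:
            raise ValueError("relative_abundance must be >= 0")
        if self.vitality not in VITALITIES:
            raise ValueError(f"unknown vitality {self.vitality!r}")
        if self.ptr < 1.0:
            raise ValueError("ptr must be >= 1")
        if self.ter_position is None:
            object.__setattr__(
                self, "ter_position",
                (self.ori_position + self.genome_length // 2) % self.genome_length)
        if self.ori_position == self.ter_position:
            raise ValueError("ori and ter positions must differ")
        if self.vitality == "living":
            d = self.damage
            if d.delta_ss > 0.01 or d.blocker_rate > 1e-4 or d.nick_rate > 1e-4:
                raise ValueError("living populations must have ~zero lesion rates")
            if d.frag_mu <= math.log(10_380.0):
                raise ValueError(
                    "living populations must have >10 kb median fragments")


@dataclass(frozen=True)
class LibrarySpec:
    """One sequencing library of the 2x2 design (fraction x +/- repair)."""

    fraction: str  # iDNA | eDNA
    repaired: bool
    read_length: int = 100
    target_depth: float = 8.0
    repair_efficiency: float = 1.0  # rho, applied per lesion when repaired
    block_prob: float = 0.9  # pi, per blocking lesion
    seq_error_rate: float = 0.001
    seed: int = 0
    yield_factor: float = 1.0  # <1 mimics the lower yield of repaired libraries
    max_insert: int = 500  # longer fragments are lab-sheared before reading

    def __post_init__(self) -> None:
        if self.fraction not in ("iDNA", "eDNA"):
            raise ValueError("fraction must be 'iDNA' or 'eDNA'")
        if self.read_length < 30:
            raise ValueError("read_length must be >= 30")
        if not (0.0 <= self.repair_efficiency <= 1.0):
            raise ValueError("repair_efficiency must be in [0, 1]")
        if not (0.0 <= self.block_prob <= 1.0):
            raise ValueError("block_prob must be in [0, 1]")
        if not (0.0 <= self.seq_error_rate < 1.0):
            raise ValueError("seq_error_rate must be in [0, 1)")
        if not (0.0 < self.yield_factor <= 1.0):
            raise ValueError("yield_factor must be in (0, 1]")

    @property
    def library_id(self) -> str:
        return f"{self.fraction}_{'repaired' if self.repaired else 'unrepaired'}"


@dataclass(frozen=True, slots=True)
class Lesion:
    """A typed lesion at a 0-based offset from the fragment's own 5' end."""

    offset: int
    kind: str  # deam_C | deam_G | abasic | nick | blocker


@dataclass(frozen=True, slots=True)
class Fragment:
    """A taphonomically processed DNA fragment (0-based half-open coords)."""

    genome_id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    lesions: tuple[Lesion, ...] = ()

    @property
    def length(self) -> int:
        return self.end - self.start

    def n_blocking(self) -> int:
        return sum(1 for l in self.lesions if l.kind in BLOCKING_KINDS)


@dataclass(frozen=True, slots=True)
class SimRead:
    """A sequenced read with its true alignment and lesion bookkeeping."""

    name: str
    genome_id: str
    ref_start: int  # genome coords of the aligned read, 0-based half-open
    ref_end: int
    strand: str
    seq: str  # read (5'->3') orientation, as written to FASTQ
    frag_index: int
    n_deam_in_read: int
    n_seq_errors: int


# --------------------------------------------------------------------------
# reference genomes
# --------------------------------------------------------------------------


def generate_reference_genomes(specs: Sequence[PopulationSpec],
                               seed: int) -> dict[str, str]:
    """Draw i.i.d. reference sequences with the requested GC fraction.

    Deterministic given ``seed``; each genome uses its own child stream so
    adding a population does not perturb the others.
    """
    genomes: dict[str, str] = {}
    for spec in specs:
        rng = child_rng(seed, "genome", spec.genome_id)
        gc = spec.gc_fraction
        p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
        arr = rng.choice(_BASES, size=spec.genome_length, p=p)
        genomes[spec.genome_id] = arr.tobytes().decode("ascii")
    return genomes


# --------------------------------------------------------------------------
# taphonomy
# --------------------------------------------------------------------------

_KIND_CODES = {0: "deam_C", 1: "deam_G", 2: "nick", 3: "blocker"}


def _skewed_starts(rng: np.random.Generator, n: int, genome_length: int,
                   lengths: np.ndarray, spec: PopulationSpec) -> np.ndarray:
    """Fragment start positions, weighted by the ori->ter replication skew.

    Coverage follows the log-linear gradient of a replicating population:
    weight(x) = ptr ** (1 - d(x)) where d(x) is the circular distance to the
    origin as a fraction of the half-genome.  ptr == 1 reduces to uniform.
    """
    G = genome_length
    max_start = np.maximum(G - lengths, 0)
    if spec.ptr == 1.0:
        pos = rng.integers(0, G, size=n)
    else:
        ncell = min(1000, G)
        centers = (np.arange(ncell) + 0.5) * (G / ncell)
        dist = np.abs(centers - spec.ori_position)
        d = np.minimum(dist, G - dist) / (G / 2)
        w = spec.ptr ** (1.0 - d)
        w /= w.sum()
        cell = rng.choice(ncell, size=n, p=w)
        pos = ((cell + rng.random(n)) * (G / ncell)).astype(np.int64)
    return np.minimum(pos, max_start)


def simulate_taphonomy(genome: str, spec: PopulationSpec, age_yr: float,
                       seed: int, n_fragments: int | None = None
                       ) -> list[Fragment]:
    """Fragment a genome and deposit lesions according to its damage params.

    Fragment lengths are lognormal(frag_mu, frag_sigma) truncated to
    [30 bp, genome length]; deamination follows the overhang-decay law from
    both termini; nicks and blocking lesions are Poisson in fragment length.
    ``age_yr`` is validated and recorded by callers as metadata: the lesion
    intensity itself is carried entirely by ``spec.damage`` (scenarios encode
    age through the parameters).
    """
    if not genome:
        raise ValueError("empty genome")
    if len(genome) != spec.genome_length:
        raise ValueError("genome length does not match spec.genome_length")
    if age_yr < 0:
        raise ValueError("age_yr must be >= 0")
    d = spec.damage
    if n_fragments is None:
        mean_len = math.exp(d.frag_mu + 0.5 * d.frag_sigma**2)
        n_fragments = max(100, math.ceil(5.0 * spec.genome_length / mean_len))

    rng = child_rng(seed, "taphonomy", spec.genome_id)
    G = spec.genome_length
    garr = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)

    lengths = rng.lognormal(d.frag_mu, d.frag_sigma, size=n_fragments)
    lengths = np.clip(np.round(lengths), 30, G).astype(np.int64)
    starts = _skewed_starts(rng, n_fragments, G, lengths, spec)
    ends = starts + lengths
    is_rev = rng.random(n_fragments) < 0.5

    les_fid: list[np.ndarray] = []
    les_off: list[np.ndarray] = []
    les_kind: list[np.ndarray] = []

    # deamination: chunked flat scan over all fragment positions
    if d.delta_ss > 0 or d.delta_ds > 0:
        chunk_limit = 4_000_000
        i0 = 0
        while i0 < n_fragments:
            i1 = i0
            tot = 0
            while i1 < n_fragments and tot + lengths[i1] <= chunk_limit:
                tot += lengths[i1]
                i1 += 1
            i1 = max(i1, i0 + 1)
            lens = lengths[i0:i1]
            total = int(lens.sum())
            fid = np.repeat(np.arange(i0, i1), lens)
            cs = np.concatenate(([0], np.cumsum(lens)[:-1]))
            off = np.arange(total, dtype=np.int64) - np.repeat(cs, lens)
            rev = is_rev[fid]
            gpos = np.where(rev, ends[fid] - 1 - off, starts[fid] + off)
            base = garr[gpos]
            base = np.where(rev, _COMP[base], base)
            L = lengths[fid]
            p5 = d.delta_ds + (d.delta_ss - d.delta_ds) * d.q**off
            hit5 = (base == ord("C")) & (rng.random(total) < p5)
            p3 = d.delta_ds + (d.delta_ss - d.delta_ds) * d.q ** (L - 1 - off)
            hit3 = (base == ord("G")) & (rng.random(total) < p3)
            for hits, code in ((hit5, 0), (hit3, 1)):
                idx = np.flatnonzero(hits)
                if idx.size:
                    les_fid.append(fid[idx])
                    les_off.append(off[idx])
                    les_kind.append(np.full(idx.size, code, dtype=np.int8))
            i0 = i1

    # nicks and blocking lesions: Poisson per fragment, uniform offsets
    for rate, code in ((d.nick_rate, 2), (d.blocker_rate, 3)):
        if rate > 0:
            counts = rng.poisson(rate * lengths)
            tot = int(counts.sum())
            if tot:
                fid = np.repeat(np.arange(n_fragments), counts)
                off = np.floor(rng.random(tot) * lengths[fid]).astype(np.int64)
                les_fid.append(fid)
                les_off.append(off)
                les_kind.append(np.full(tot, code, dtype=np.int8))

    per_frag: list[list[Lesion]] = [[] for _ in range(n_fragments)]
    if les_fid:
        fid = np.concatenate(les_fid)
        off = np.concatenate(les_off)
        kind = np.concatenate(les_kind)
        order = np.lexsort((off, fid))
        for i in order:
            per_frag[fid[i]].append(Lesion(int(off[i]), _KIND_CODES[int(kind[i])]))

    strand = np.where(is_rev, "-", "+")
    return [
        Fragment(spec.genome_id, int(starts[i]), int(ends[i]), str(strand[i]),
                 tuple(per_frag[i]))
        for i in range(n_fragments)
    ]


# --------------------------------------------------------------------------
# iDNA/eDNA partitioning and in-vitro repair
# --------------------------------------------------------------------------


def partition_idna_edna(fragments: Sequence[Fragment], vitality: str,
                        leakage: float | None = None, seed: int = 0
                        ) -> tuple[list[Fragment], list[Fragment]]:
    """Route fragments into the (iDNA, eDNA) extraction pools.

    Lysed populations go to eDNA (iDNA leakage = ``leakage``); living and
    intact-dead populations go to iDNA with an eDNA leakage.  Pools are
    disjoint and jointly exhaustive.
    """
    if vitality not in VITALITIES:
        raise ValueError(f"unknown vitality {vitality!r}")
    if leakage is None:
        leakage = DEFAULT_LEAKAGE[vitality]
    if not (0.0 <= leakage <= 1.0):
        raise ValueError("leakage must be in [0, 1]")
    if vitality == "lysed" and leakage > 0.1:
        raise ValueError("lysed populations must route >= 90% to eDNA")
    rng = child_rng(seed, "partition", vitality)
    u = rng.random(len(fragments))
    p_edna = (1.0 - leakage) if vitality == "lysed" else leakage
    idna, edna = [], []
    for frag, ui in zip(fragments, u):
        (edna if ui < p_edna else idna).append(frag)
    return idna, edna


def apply_repair(fragments: Sequence[Fragment], rho: float, seed: int = 0
                 ) -> list[Fragment]:
    """In-vitro enzymatic repair: each lesion independently reverted w.p. rho.

    Models a glycosylase/endonuclease/polymerase/ligase cocktail: deaminated
    cytosines are excised and re-filled from the intact strand, abasic sites,
    nicks and dimers are resolved.  rho=0 is the identity; the input list is
    not mutated.
    """
    if not (0.0 <= rho <= 1.0):
        raise ValueError("rho must be in [0, 1]")
    if rho == 0.0:
        return [replace(f) for f in fragments]
    rng = child_rng(seed, "repair")
    out = []
    for frag in fragments:
        if not frag.lesions:
            out.append(frag)
            continue
        if rho == 1.0:
            kept: tuple[Lesion, ...] = ()
        else:
            u = rng.random(len(frag.lesions))
            kept = tuple(l for l, ui in zip(frag.lesions, u) if ui >= rho)
        out.append(replace(frag, lesions=kept))
    return out


def conversion_probability(fragment: Fragment, block_prob: float) -> float:
    """P(fragment converts to the library) = (1 - pi)^(# blocking lesions)."""
    return (1.0 - block_prob) ** fragment.n_blocking()


# --------------------------------------------------------------------------
# sequencing
# --------------------------------------------------------------------------


@dataclass
class SequencedLibrary:
    """Reads of one library plus the ground-truth table."""

    spec: LibrarySpec
    reads: list[SimRead]
    truth: pd.DataFrame
    genome_lengths: dict[str, int]

    def write_fastq(self, path) -> None:
        with open(path, "w") as fh:
            for r in self.reads:
                fh.write(f"@{r.name}\n{r.seq}\n+\n{'I' * len(r.seq)}\n")

    def write_sam(self, path, sort: bool = True) -> None:
        from . import io as _io

        _io.write_sam(self.reads, self.genome_lengths, path, sort=sort)

    def intervals(self, genome_id: str) -> list[tuple[int, int]]:
        """True alignment intervals of this library's reads on one genome."""
        return [(r.ref_start, r.ref_end) for r in self.reads
                if r.genome_id == genome_id]


def _damaged_fragment_array(garr: np.ndarray, frag: Fragment) -> np.ndarray:
    """Fragment sequence (5'->3', uint8) with surviving deaminations applied."""
    if frag.strand == "+":
        seq = garr[frag.start:frag.end].copy()
    else:
        seq = _COMP[garr[frag.start:frag.end]][::-1].copy()
    for les in frag.lesions:
        if les.kind == "deam_C":
            seq[les.offset] = ord("T")
        elif les.kind == "deam_G":
            seq[les.offset] = ord("A")
    return seq


def sequence_library(fragments: Sequence[Fragment],
                     genome_map: Mapping[str, str],
                     spec: LibrarySpec,
                     abundances: Mapping[str, float] | None = None
                     ) -> SequencedLibrary:
    """Convert, sample and sequence a fragment pool into one library.

    A fragment converts with probability (1 - pi)^(#blocking lesions); the
    number of read attempts per genome is target_depth * genome_length /
    read_length (times ``yield_factor``), so realized depth shrinks with the
    blocked fraction -- the mechanism behind the repaired/unrepaired
    completeness contrast.  ``abundances`` (mean-normalised) scale the
    per-genome depth.  Short fragments (<= max_insert) are read from
    their own 5' terminus (which carries the ancient damage signature);
    longer fragments are lab-sheared, so the read starts at a uniform
    position with a fresh, undamaged end.
    """
    depths_requested = spec.target_depth > 0
    if depths_requested and len(fragments) == 0:
        raise ValueError("fragment pool is empty but target_depth > 0")

    rng = child_rng(spec.seed, "library", spec.library_id)
    genome_arrays = {g: np.frombuffer(s.encode("ascii"), dtype=np.uint8)
                     for g, s in genome_map.items()}
    genome_lengths = {g: len(s) for g, s in genome_map.items()}

    by_genome: dict[str, list[int]] = {g: [] for g in genome_map}
    for i, frag in enumerate(fragments):
        if frag.genome_id not in by_genome:
            raise KeyError(f"fragment references unknown genome {frag.genome_id!r}")
        by_genome[frag.genome_id].append(i)

    reads: list[SimRead] = []
    truth_rows: list[tuple] = []
    seq_chunks: list[np.ndarray] = []
    damaged_cache: dict[int, np.ndarray] = {}

    if abundances:
        mean_ab = sum(abundances.get(g, 1.0) for g in genome_map) / len(genome_map)
        weight = {g: abundances.get(g, 1.0) / mean_ab for g in genome_map}
    else:
        weight = {g: 1.0 for g in genome_map}

    for gid in genome_map:
        pool = by_genome[gid]
        n_draw = int(round(spec.target_depth * weight[gid]
                           * genome_lengths[gid]
                           / spec.read_length * spec.yield_factor))
        if n_draw == 0 or not pool:
            continue
        pool_arr = np.asarray(pool)
        draws = pool_arr[rng.integers(0, len(pool_arr), size=n_draw)]
        conv_p = np.array([conversion_probability(fragments[i], spec.block_prob)
                           for i in draws])
        kept = draws[rng.random(n_draw) < conv_p]
        garr = genome_arrays[gid]
        for j, fi in enumerate(kept):
            frag = fragments[fi]
            L = frag.length
            rl = min(spec.read_length, L)
            if L <= spec.max_insert:
                u = 0  # ancient terminus: damage signature preserved
            else:
                u = int(rng.integers(0, L - rl + 1))
            arr = damaged_cache.get(fi)
            if arr is None:
                arr = _damaged_fragment_array(garr, frag)
                damaged_cache[fi] = arr
            window = arr[u:u + rl].copy()
            n_deam = sum(1 for l in frag.lesions
                         if l.kind in ("deam_C", "deam_G") and u <= l.offset < u + rl)
            if frag.strand == "+":
                ref_start, ref_end = frag.start + u, frag.start + u + rl
            else:
                ref_start, ref_end = frag.end - u - rl, frag.end - u
            name = f"{gid}|f{fi}|r{j}"
            seq_chunks.append(window)
            reads.append(SimRead(name, gid, ref_start, ref_end, frag.strand,
                                 "", fi, n_deam, 0))
            truth_rows.append((name, gid, frag.start, frag.end, frag.strand,
                               L, ref_start, ref_end, n_deam,
                               frag.n_blocking()))

    # sequencing errors, applied flat over all reads at once
    if reads:
        flat = np.concatenate(seq_chunks)
        lens = np.array([c.size for c in seq_chunks])
        if spec.seq_error_rate > 0:
            err = rng.random(flat.size) < spec.seq_error_rate
            idx = np.flatnonzero(err)
            if idx.size:
                shift = rng.integers(1, 4, size=idx.size)
                flat[idx] = _BASES[(_BASE_INDEX[flat[idx]] + shift) % 4]
        bounds = np.concatenate(([0], np.cumsum(lens)))
        finished: list[SimRead] = []
        for k, r in enumerate(reads):
            piece = flat[bounds[k]:bounds[k + 1]]
            n_err = int((piece != seq_chunks[k]).sum())
            finished.append(replace(r, seq=piece.tobytes().decode("ascii"),
                                    n_seq_errors=n_err))
        reads = finished

    truth = pd.DataFrame(truth_rows, columns=[
        "read_name", "genome_id", "frag_start", "frag_end", "strand",
        "frag_length", "read_start", "read_end", "n_deam_in_read",
        "n_blocking"])
    return SequencedLibrary(spec=spec, reads=reads, truth=truth,
                            genome_lengths=genome_lengths)
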