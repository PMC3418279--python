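"""Synthetic promoter universes with planted degenerate motifs.

Every pipeline stage is testable without genome downloads: this module
generates i.i.d.-background promoter sets (AT-rich by default, matching the
base composition regime of plant promoters), plants concrete instances of
degenerate motifs into chosen fractions of a cluster and of the background
genome with configurable positional placement (uniform, or concentrated near
the TSS), and emits a machine-readable truth table for recovery scoring.
A two-species variant derives an "ortholog" genome by per-base substitution,
optionally protecting planted instances from mutation (conserved motifs).

All randomness flows from a single seed through named spawned streams
(background / cluster / plants / mutation), so identical specs give
byte-identical FASTA output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple, Union

import numpy as np
import pandas as pd

from .alphabet import ALPHA11, MotifAlphabet
from .comparative import OrthologMap
from .promoters import PromoterSet

__all__ = [
    "PlantedMotif",
    "FixtureSpec",
    "generate_fixture",
    "generate_ortholog_fixture",
    "OrthologFixture",
]

_BASES = "ACGT"


@dataclass(frozen=True)
class PlantedMotif:
    """One motif to plant.

    ``positions`` is either ``"uniform"`` or ``("tss_biased", peak_start,
    peak_end, weight)``: with probability ``weight`` the instance start is
    uniform on [peak_start, peak_end] (1-based, clipped to the valid range),
    otherwise uniform over all valid starts.
    """

    motif: str
    cluster_fraction: float = 0.7
    genome_fraction: float = 0.0
    positions: Union[str, Tuple] = "uniform"

    def __post_init__(self) -> None:
        for frac in (self.cluster_fraction, self.genome_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.positions != "uniform":
            tag, lo, hi, weight = self.positions
            if tag != "tss_biased" or lo > hi or not 0 <= weight <= 1:
                raise ValueError(f"invalid position model {self.positions!r}")


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic promoter universe."""

    n_genome_promoters: int = 200
    window_length: int = 1000
    cluster_size: int = 50
    background: Tuple[float, float, float, float] = (0.33, 0.17, 0.17, 0.33)
    plants: Tuple[PlantedMotif, ...] = ()
    seed: int = 0
    alphabet: MotifAlphabet = ALPHA11
    substitution_rate: float = 0.15  # two-species divergence (~85% identity)
    species: Tuple[str, str] = ("speciesA", "speciesB")

    def __post_init__(self) -> None:
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")
        if self.cluster_size > self.n_genome_promoters:
            raise ValueError("cluster_size exceeds the genome size")
        if not 0.0 <= self.substitution_rate <= 0.5:
            raise ValueError("substitution_rate must lie in [0, 0.5]")
        for plant in self.plants:
            self.alphabet.canonicalize(plant.motif)  # validates letters


def _sample_instance(motif: str, alphabet: MotifAlphabet, rng) -> str:
    """A concrete word drawn uniformly from the motif's match set."""
    word = alphabet.canonicalize(motif)
    return "".join(
        rng.choice(sorted(alphabet.matches_of[c])) for c in word
    )


def _sample_start(plant: PlantedMotif, s_max: int, rng) -> int:
    if plant.positions == "uniform":
        return int(rng.integers(1, s_max + 1))
    _tag, lo, hi, weight = plant.positions
    lo, hi = max(1, lo), min(s_max, hi)
    if rng.random() < weight:
        return int(rng.integers(lo, hi + 1))
    return int(rng.integers(1, s_max + 1))


def generate_fixture(
    spec: FixtureSpec,
) -> Tuple[PromoterSet, List[str], pd.DataFrame]:
    """Generate (genome promoter set, cluster id list, truth table).

    The truth table has one row per planted instance: ``gene, motif,
    instance, start, in_cluster``.  Instances overwrite the background (and,
    for multiple plants, possibly each other -- plant sparingly).
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_bg, rng_cluster, rng_plants, _ = (
        np.random.default_rng(c) for c in ss.spawn(4)
    )
    n, w = spec.n_genome_promoters, spec.window_length
    ids = [f"g{i:05d}" for i in range(n)]
    base_idx = rng_bg.choice(4, size=(n, w), p=spec.background).astype(np.uint8)

    cluster_rows = np.sort(
        rng_cluster.choice(n, size=spec.cluster_size, replace=False)
    )
    cluster_set = set(cluster_rows.tolist())
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    seq_bytes = lut[base_idx]

    truth_rows = []
    for plant in spec.plants:
        word = spec.alphabet.canonicalize(plant.motif)
        s_max = w - len(word) + 1
        n_cluster = round(plant.cluster_fraction * spec.cluster_size)
        targets = list(
            rng_plants.choice(cluster_rows, size=n_cluster, replace=False)
        )
        flags = [True] * n_cluster
        others = np.array(
            [i for i in range(n) if i not in cluster_set], dtype=np.int64
        )
        n_genome = round(plant.genome_fraction * others.size)
        if n_genome:
            targets += list(rng_plants.choice(others, size=n_genome, replace=False))
            flags += [False] * n_genome
        for row, in_cluster in zip(targets, flags):
            instance = _sample_instance(word, spec.alphabet, rng_plants)
            start = _sample_start(plant, s_max, rng_plants)
            seq_bytes[row, start - 1 : start - 1 + len(word)] = np.frombuffer(
                instance.encode(), dtype=np.uint8
            )
            truth_rows.append(
                {
                    "gene": ids[row],
                    "motif": word,
                    "instance": instance,
                    "start": start,
                    "in_cluster": in_cluster,
                }
            )
    sequences = [bytes(seq_bytes[i]).decode() for i in range(n)]
    genome = PromoterSet(ids, sequences, window_length=w, species=spec.species[0])
    cluster_ids = [ids[i] for i in cluster_rows]
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "motif", "instance", "start", "in_cluster"]
    )
    return genome, cluster_ids, truth


@dataclass
class OrthologFixture:
    """Two-species fixture: mutated ortholog genome plus the mapping."""

    species1: PromoterSet
    species2: PromoterSet
    orthologs: OrthologMap
    cluster_ids: List[str]
    truth: pd.DataFrame


def generate_ortholog_fixture(
    spec: FixtureSpec, protect_plants: bool = True
) -> OrthologFixture:
    """Generate two diverged promoter sets linked by a one-to-one ortholog map.

    Species-2 promoters are per-base mutated copies of species-1 promoters
    (substitution to a uniformly random different base at
    ``spec.substitution_rate``).  With ``protect_plants`` the planted motif
    instances are copied back unmutated (conserved motifs); without it they
    diverge like background.
    """
    genome1, cluster_ids, truth = generate_fixture(spec)
    rng_mut = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(4)[3])
    n, w = spec.n_genome_promoters, spec.window_length

    lut_idx = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lut_idx[ord(b)] = i
    seq1 = np.frombuffer(
        "".join(genome1.sequences).encode(), dtype=np.uint8
    ).reshape(n, w)
    idx = lut_idx[seq1]
    mutate = rng_mut.random((n, w)) < spec.substitution_rate
    shift = rng_mut.integers(1, 4, size=(n, w), dtype=np.uint8)
    idx2 = np.where(mutate, (idx + shift) % 4, idx)
    lut = np.frombuffer(_BASES.encode(), dtype=np.uint8)
    seq2 = lut[idx2]

    row_of = {g: i for i, g in enumerate(genome1.gene_ids)}
    if protect_plants:
        for rec in truth.itertuples():
            row = row_of[rec.gene]
            sl = slice(rec.start - 1, rec.start - 1 + len(rec.instance))
            seq2[row, sl] = seq1[row, sl]

    ids2 = [f"{g}_o" for g in genome1.gene_ids]
    genome2 = PromoterSet(
        ids2,
        [bytes(seq2[i]).decode() for i in range(n)],
        window_length=w,
        species=spec.species[1],
    )
    orthologs = OrthologMap(
        list(zip(genome1.gene_ids, ids2)), provenance="synthetic fixture"
    )
    return OrthologFixture(genome1, genome2, orthologs, cluster_ids, truth)
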