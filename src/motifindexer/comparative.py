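"""Two-genome comparative motif analyses.

Two complementary strategies, neither of which aligns promoter sequences:

* **Conserved p-values over orthologous promoter sets.**  A cluster of
  co-expressed genes is restricted to genes with known orthologs; the
  enrichment analysis runs independently in each species' orthologous
  promoters, and each oligo is assigned the *larger* (worse) of its two
  p-values as a conserved p-value.  True motifs stay significant in both
  close relatives while false positives rarely repeat, so the p-value cutoff
  can be relaxed (1e-5) relative to single-species analysis.

* **Genome-wide position-bias scan.**  TSS-proximal position bias is itself
  evidence for function, so 8-mers (restricted to at most two degenerate
  letters from {r, y, s, w, n}) are ranked by their genome-wide z-score in
  each species, and the biased sets of the two genomes are intersected.

Ortholog detection (protein alignment, identity/length filters) happens
upstream; this module consumes a precomputed two-column gene-id table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .alphabet import ALPHA11, MotifAlphabet, codes_of_digits, decode, rc_codes
from .indexing import OligoCountIndex, occurrence_index
from .pipeline import cluster_candidates
from .position_bias import zscores_from_moments
from .promoters import PromoterSet, subset_by_ids

__all__ = [
    "OrthologMap",
    "conserved_pvalue",
    "conserved_motif_analysis",
    "restricted_degenerate_codes",
    "genome_bias_scan",
    "intersect_biased",
]


@dataclass
class OrthologMap:
    """One-to-one gene-id mapping between two species."""

    pairs: List[Tuple[str, str]]
    provenance: str = ""
    _fwd: Dict[str, str] = field(init=False, repr=False)
    _rev: Dict[str, str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        fwd: Dict[str, str] = {}
        rev: Dict[str, str] = {}
        for a, b in self.pairs:
            if a in fwd or b in rev:
                raise ValueError(
                    f"ortholog map is not one-to-one (duplicate in pair {(a, b)})"
                )
            fwd[a] = b
            rev[b] = a
        self._fwd, self._rev = fwd, rev

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._fwd

    def ortholog_of(self, gene_id: str) -> str:
        return self._fwd[gene_id]

    @classmethod
    def read_tsv(cls, path, provenance: str = "") -> "OrthologMap":
        pairs = []
        with open(path) as fh:
            for line in fh:
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                cols = line.split("\t")
                if len(cols) < 2:
                    raise ValueError(f"ortholog table line lacks two columns: {line!r}")
                pairs.append((cols[0], cols[1]))
        return cls(pairs, provenance or str(path))

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            for a, b in self.pairs:
                fh.write(f"{a}\t{b}\n")


def conserved_pvalue(p1: float, p2: float) -> float:
    """Conserved p-value of an oligo tested in two species: max(p1, p2)."""
    if not (0 <= p1 <= 1 and 0 <= p2 <= 1):
        raise ValueError("p-values must lie in [0, 1]")
    return max(p1, p2)


def _species_candidate_table(
    cluster: PromoterSet,
    genome_index: OligoCountIndex,
    cutoff: float,
) -> pd.DataFrame:
    """Per-species candidates keyed by canonical (RC-invariant) code.

    For each reverse-complement pair the better-ranked member's statistics
    are kept, so the cross-species join is orientation-independent.
    """
    alphabet, L = genome_index.alphabet, genome_index.word_length
    cand, _meta = cluster_candidates(cluster, genome_index, cutoff)
    codes = cand["code"].to_numpy()
    occ = occurrence_index(cluster, alphabet, L)
    n = occ.occurrences[codes].astype(np.int64)
    pos_sum = occ.pos_sum[codes].astype(np.int64)
    del occ
    z = zscores_from_moments(n, pos_sum, cluster.window_length, L)
    mean_pos = np.divide(pos_sum, n, out=np.full(len(cand), np.nan), where=n > 0)
    cand = cand.assign(z=z, mean_position=mean_pos)
    rc = rc_codes(codes, L, alphabet)
    cand = cand.assign(canonical=np.minimum(codes, rc))
    cand = cand.sort_values(["pvalue", "code"], kind="stable")
    cand = cand.drop_duplicates("canonical", keep="first")
    return cand.set_index("canonical")


def conserved_motif_analysis(
    cluster_ids: Sequence[str],
    orthologs: OrthologMap,
    promoters1: PromoterSet,
    promoters2: PromoterSet,
    genome_index1: OligoCountIndex,
    genome_index2: OligoCountIndex,
    cutoff: float = 1e-5,
) -> pd.DataFrame:
    """Conserved-p-value motif discovery over orthologous promoter sets.

    The cluster is restricted to genes with orthologous promoters in the
    second species; enrichment runs per species on the restricted sets; the
    per-oligo join assigns ``max(p1, p2)`` and keeps oligos with conserved
    p-value at or below ``cutoff``, sorted ascending.
    """
    alphabet, L = genome_index1.alphabet, genome_index1.word_length
    if genome_index2.alphabet is not alphabet or genome_index2.word_length != L:
        raise ValueError("genome indexes use different codecs")
    ids1 = [
        g
        for g in cluster_ids
        if g in promoters1 and g in orthologs and orthologs.ortholog_of(g) in promoters2
    ]
    if not ids1:
        raise ValueError("no cluster gene has an orthologous promoter in both species")
    ids2 = [orthologs.ortholog_of(g) for g in ids1]
    cluster1 = subset_by_ids(promoters1, ids1)
    cluster2 = subset_by_ids(promoters2, ids2)

    t1 = _species_candidate_table(cluster1, genome_index1, cutoff)
    t2 = _species_candidate_table(cluster2, genome_index2, cutoff)
    joined = t1.join(t2, how="inner", lsuffix="_1", rsuffix="_2")
    if not len(joined):
        return _empty_conserved_frame(promoters1.species, promoters2.species)
    conserved = np.maximum(joined["pvalue_1"], joined["pvalue_2"])
    joined = joined.assign(conserved_pvalue=conserved)
    joined = joined[joined["conserved_pvalue"] <= cutoff]
    joined = joined.sort_values(
        ["conserved_pvalue", "pvalue_1"], kind="stable"
    ).reset_index()
    out = pd.DataFrame(
        {
            "motif": [decode(int(c), L, alphabet) for c in joined["canonical"]],
            "pvalue_1": joined["pvalue_1"],
            "mean_position_1": joined["mean_position_1"],
            "z_1": joined["z_1"],
            "pvalue_2": joined["pvalue_2"],
            "mean_position_2": joined["mean_position_2"],
            "z_2": joined["z_2"],
            "conserved_pvalue": joined["conserved_pvalue"],
        }
    )
    out.attrs["species"] = (promoters1.species, promoters2.species)
    out.attrs["n_cluster_orthologs"] = len(ids1)
    return out


def _empty_conserved_frame(sp1: str, sp2: str) -> pd.DataFrame:
    out = pd.DataFrame(
        columns=[
            "motif",
            "pvalue_1",
            "mean_position_1",
            "z_1",
            "pvalue_2",
            "mean_position_2",
            "z_2",
            "conserved_pvalue",
        ]
    )
    out.attrs["species"] = (sp1, sp2)
    return out


# -- genome-wide position-bias scan ----------------------------------------


def restricted_degenerate_codes(
    alphabet: MotifAlphabet = ALPHA11,
    word_length: int = 8,
    max_degenerate: int = 2,
    allowed_wobbles: str = "ryswn",
) -> np.ndarray:
    """Codes of all words with at most ``max_degenerate`` wobble letters.

    Wobbles are restricted to ``allowed_wobbles``; all other positions are
    concrete bases.  For 8-mers with <=2 of {r,y,s,w,n} this enumerates
    C(8,0)*4^8 + C(8,1)*5*4^7 + C(8,2)*5^2*4^6 = 3,588,096 words.
    """
    from itertools import combinations, product

    wob_digits = [alphabet.digit_of[w] for w in allowed_wobbles]
    base_digits = np.arange(4, dtype=np.int64)
    chunks = []
    for n_wob in range(max_degenerate + 1):
        for wob_pos in combinations(range(word_length), n_wob):
            concrete_pos = [p for p in range(word_length) if p not in wob_pos]
            n_concrete_combos = 4 ** len(concrete_pos)
            base_part = (
                np.stack(
                    np.meshgrid(
                        *([base_digits] * len(concrete_pos)), indexing="ij"
                    ),
                    axis=-1,
                ).reshape(n_concrete_combos, len(concrete_pos))
                if concrete_pos
                else np.zeros((1, 0), dtype=np.int64)
            )
            for wob_combo in product(wob_digits, repeat=n_wob):
                digits = np.empty(
                    (n_concrete_combos, word_length), dtype=np.int64
                )
                digits[:, concrete_pos] = base_part
                for p, d in zip(wob_pos, wob_combo):
                    digits[:, p] = d
                chunks.append(codes_of_digits(digits, alphabet))
    return np.concatenate(chunks)


def genome_bias_scan(
    promoters: PromoterSet,
    z_cutoff: float = 3.0,
    alphabet: MotifAlphabet = ALPHA11,
    word_length: int = 8,
    max_degenerate: int = 2,
    allowed_wobbles: str = "ryswn",
) -> pd.DataFrame:
    """Genome-wide scan for TSS-position-biased motifs.

    Enumerates the restricted-degeneracy words, gathers all occurrence
    positions over every promoter in the genome, computes the mean position
    and the uniform-model z-score, and returns words with z >= ``z_cutoff``,
    reverse-complement-deduplicated and sorted by decreasing z.
    """
    occ_index = occurrence_index(promoters, alphabet, word_length)
    codes = restricted_degenerate_codes(
        alphabet, word_length, max_degenerate, allowed_wobbles
    )
    n = occ_index.occurrences[codes].astype(np.int64)
    pos_sum = occ_index.pos_sum[codes].astype(np.int64)
    del occ_index
    present = n > 0
    codes, n, pos_sum = codes[present], n[present], pos_sum[present]
    z = zscores_from_moments(n, pos_sum, promoters.window_length, word_length)
    keep = z >= z_cutoff
    codes, n, pos_sum, z = codes[keep], n[keep], pos_sum[keep], z[keep]

    order = np.lexsort((codes, -z))
    codes, n, pos_sum, z = codes[order], n[order], pos_sum[order], z[order]
    rc = rc_codes(codes, word_length, alphabet)
    keep_mask = np.ones(codes.size, dtype=bool)
    seen = set()
    for i, (c, r) in enumerate(zip(codes.tolist(), rc.tolist())):
        if (r in seen and r != c) or c in seen:
            keep_mask[i] = False
            continue
        seen.add(c)
    codes, n, pos_sum, z = (
        codes[keep_mask],
        n[keep_mask],
        pos_sum[keep_mask],
        z[keep_mask],
    )
    canonical = np.minimum(codes, rc_codes(codes, word_length, alphabet))
    out = pd.DataFrame(
        {
            "motif": [decode(int(c), word_length, alphabet) for c in canonical],
            "instances": n,
            "mean_position": pos_sum / np.maximum(n, 1),
            "z": z,
        }
    ).reset_index(drop=True)
    out.attrs.update(
        {
            "species": promoters.species,
            "alphabet": alphabet.name,
            "word_length": word_length,
            "max_degenerate": max_degenerate,
            "allowed_wobbles": allowed_wobbles,
            "window_length": promoters.window_length,
            "z_cutoff": z_cutoff,
        }
    )
    return out


def intersect_biased(
    scan1: pd.DataFrame, scan2: pd.DataFrame
) -> Tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split two genome bias scans into shared and species-exclusive motifs.

    Motifs are joined by exact degenerate string (scans already report the
    canonical reverse-complement orientation).  Returns
    ``(shared, only_in_1, only_in_2)``; scan parameters must agree.
    """
    for key in ("alphabet", "word_length", "max_degenerate", "allowed_wobbles"):
        if scan1.attrs.get(key) != scan2.attrs.get(key):
            raise ValueError(f"scan parameter mismatch: {key}")
    shared = scan1.merge(scan2, on="motif", suffixes=("_1", "_2"))
    only1 = scan1[~scan1["motif"].isin(scan2["motif"])].reset_index(drop=True)
    only2 = scan2[~scan2["motif"].isin(scan1["motif"])].reset_index(drop=True)
    return shared.reset_index(drop=True), only1, only2
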