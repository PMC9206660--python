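"""Tiled peptide library design.

Proteins are cut into fixed-length peptide tiles with a constant step so
that interior residues are covered twice (85-mer tiles stepping by 45).
Every serine or threonine in a wild-type tile additionally yields a
phosphomimetic variant carrying a single S→E or T→E substitution. Tiles are
reverse-translated into codon-sampled nucleotide sequences whose first
eight nucleotides are unique across the library — the contract the read
demultiplexer relies on — and phosphomimetic variants carry a unique 9-nt
tag placed downstream of the open reading frame.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq

__all__ = [
    "PeptideRecord",
    "LibraryDesignError",
    "tile_protein",
    "phosphomimetic_variants",
    "encode_library",
    "standard_codon_choices",
    "check_prefix_unique",
    "write_library_tsv",
    "read_library_tsv",
    "write_library_fasta",
    "read_proteins_fasta",
]

TILE_LEN = 85
TILE_STEP = 45
PREFIX_LEN = 8
TAG_LEN = 9

VARIANT_CLASSES = ("wt", "phosphomimetic", "control")


class LibraryDesignError(ValueError):
    """Raised when a design constraint cannot be satisfied.

    For prefix-collision failures, ``colliding`` lists the peptide ids whose
    first eight nucleotides could not be made unique — peptides sharing
    their first three residues can exhaust the codon wobble of an 8-nt
    prefix (this is why phosphomimetic variants additionally carry a 9-nt
    tag in the assay design).
    """

    def __init__(self, message: str, colliding: Optional[list[str]] = None):
        super().__init__(message)
        self.colliding = colliding or []


@dataclass
class PeptideRecord:
    """One library member: a peptide tile and its nucleotide encoding.

    ``tile_start`` is the 0-based residue offset of the tile in its source
    protein; coordinates are half-open throughout. ``sub_position`` is the
    0-based index *within the tile* of the S/T→E substitution and is only
    set for phosphomimetic variants. ``nt_seq`` and ``tag9`` are filled in
    by :func:`encode_library`.
    """

    peptide_id: str
    source_protein: str
    tile_start: int
    aa_seq: str
    variant_class: str = "wt"
    sub_position: Optional[int] = None
    nt_seq: Optional[str] = None
    tag9: Optional[str] = None

    def __post_init__(self) -> None:
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(f"unknown variant_class {self.variant_class!r}")

    @property
    def prefix8(self) -> str:
        if self.nt_seq is None:
            raise ValueError("record has no nucleotide encoding yet")
        return self.nt_seq[:PREFIX_LEN]


def tile_protein(
    protein_seq: str,
    source: str = "protein",
    tile_len: int = TILE_LEN,
    step: int = TILE_STEP,
    variant_class: str = "wt",
) -> list[PeptideRecord]:
    """Cut a protein into overlapping fixed-length tiles.

    Tiles start at 0, ``step``, 2·``step``, …; if the last regular tile does
    not reach the C-terminus a final tile anchored at ``len - tile_len`` is
    appended so every residue is covered and all tiles keep the same length.

    Raises
    ------
    LibraryDesignError
        If the protein is shorter than ``tile_len``.
    """
    protein_seq = protein_seq.upper()
    length = len(protein_seq)
    if length < tile_len:
        raise LibraryDesignError(
            f"{source}: protein too short ({length} aa) for {tile_len}-aa tiles"
        )
    starts = list(range(0, length - tile_len + 1, step))
    if starts[-1] + tile_len < length:
        starts.append(length - tile_len)
    return [
        PeptideRecord(
            peptide_id=f"{source}_t{start:04d}",
            source_protein=source,
            tile_start=start,
            aa_seq=protein_seq[start : start + tile_len],
            variant_class=variant_class,
        )
        for start in starts
    ]


def phosphomimetic_variants(parent: PeptideRecord) -> list[PeptideRecord]:
    """All single S→E and T→E substitutions of a wild-type tile.

    One variant is produced per serine or threonine; a tile without S/T
    yields an empty list. Multi-site combinations are deliberately not
    generated.
    """
    if parent.variant_class != "wt":
        raise ValueError("phosphomimetic variants derive from wt records only")
    variants = []
    for pos, aa in enumerate(parent.aa_seq):
        if aa not in "ST":
            continue
        mutated = parent.aa_seq[:pos] + "E" + parent.aa_seq[pos + 1 :]
        variants.append(
            PeptideRecord(
                peptide_id=f"{parent.peptide_id}_pm{pos:03d}{aa}E",
                source_protein=parent.source_protein,
                tile_start=parent.tile_start,
                aa_seq=mutated,
                variant_class="phosphomimetic",
                sub_position=pos,
            )
        )
    return variants


def standard_codon_choices(table_id: int = 1) -> dict[str, list[str]]:
    """Codons per amino acid from an NCBI translation table (stops excluded)."""
    table = CodonTable.unambiguous_dna_by_id[table_id]
    choices: dict[str, list[str]] = {}
    for codon, aa in sorted(table.forward_table.items()):
        choices.setdefault(aa, []).append(codon)
    return choices


def _normalise_usage(
    codon_table: Optional[Mapping[str, Mapping[str, float]]],
) -> dict[str, tuple[list[str], np.ndarray]]:
    """Turn an aa → {codon: weight} map into sampling-ready arrays."""
    if codon_table is None:
        codon_table = {
            aa: {c: 1.0 for c in codons}
            for aa, codons in standard_codon_choices().items()
        }
    out = {}
    for aa, weights in codon_table.items():
        codons = sorted(weights)
        w = np.array([float(weights[c]) for c in codons])
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError(f"invalid codon weights for {aa!r}")
        out[aa] = (codons, w / w.sum())
    return out


def encode_library(
    records: Sequence[PeptideRecord],
    codon_table: Optional[Mapping[str, Mapping[str, float]]] = None,
    seed: int = 0,
    max_retries: int = 200,
) -> list[PeptideRecord]:
    """Assign codon-sampled nucleotide sequences and 9-nt variant tags.

    Codons are drawn independently per position, weighted by ``codon_table``
    (uniform over synonymous codons by default). If the first eight
    nucleotides collide with an already-encoded record, the first three
    codons are resampled up to ``max_retries`` times; records whose prefix
    cannot be made unique are reported together in the raised error.
    Phosphomimetic records receive a ``tag9`` unique among variants, kept
    outside the translated frame (downstream of the ORF) so the amino-acid
    sequence is untouched. Deterministic given ``seed``.
    """
    if not records:
        raise ValueError("no records to encode")
    usage = _normalise_usage(codon_table)
    rng = np.random.default_rng(seed)
    seen_prefixes: set[str] = set()
    seen_tags: set[str] = set()
    encoded: list[PeptideRecord] = []
    colliding: list[str] = []

    for rec in records:
        try:
            codons = [_draw_codon(rng, usage, aa, rec) for aa in rec.aa_seq]
        except KeyError as exc:
            raise LibraryDesignError(
                f"{rec.peptide_id}: no codons for residue {exc}"
            ) from None
        prefix = "".join(codons[:3])[:PREFIX_LEN]
        retries = 0
        while prefix in seen_prefixes and retries < max_retries:
            codons[:3] = [_draw_codon(rng, usage, aa, rec) for aa in rec.aa_seq[:3]]
            prefix = "".join(codons[:3])[:PREFIX_LEN]
            retries += 1
        if prefix in seen_prefixes:
            colliding.append(rec.peptide_id)
            continue
        seen_prefixes.add(prefix)
        tag = None
        if rec.variant_class == "phosphomimetic":
            tag = _draw_tag(rng, seen_tags)
            seen_tags.add(tag)
        encoded.append(
            dataclasses.replace(rec, nt_seq="".join(codons), tag9=tag)
        )

    if colliding:
        raise LibraryDesignError(
            "could not find unique 8-nt prefixes for: " + ", ".join(colliding),
            colliding=colliding,
        )
    return encoded


def _draw_codon(rng, usage, aa: str, rec: PeptideRecord) -> str:
    if aa not in usage:
        raise KeyError(aa)
    codons, probs = usage[aa]
    return codons[rng.choice(len(codons), p=probs)]


def _draw_tag(rng, seen: set[str], max_retries: int = 1000) -> str:
    for _ in range(max_retries):
        tag = "".join("ACGT"[i] for i in rng.integers(0, 4, TAG_LEN))
        if tag not in seen:
            return tag
    raise LibraryDesignError("exhausted unique 9-nt tags")


def check_prefix_unique(records: Iterable[PeptideRecord]) -> None:
    """Validate the demultiplexing contract: distinct first-8-nt prefixes."""
    seen: dict[str, str] = {}
    for rec in records:
        p = rec.prefix8
        if p in seen:
            raise LibraryDesignError(
                f"duplicate 8-nt prefix {p}: {seen[p]} vs {rec.peptide_id}"
            )
        seen[p] = rec.peptide_id


def translate_orf(nt_seq: str) -> str:
    return str(Seq(nt_seq).translate())


# ---------------------------------------------------------------------------
# I/O

_TSV_COLUMNS = [
    "peptide_id",
    "source_protein",
    "tile_start",
    "variant_class",
    "sub_position",
    "aa_seq",
    "nt_seq",
    "tag9",
]


def write_library_tsv(records: Sequence[PeptideRecord], path: str | Path) -> None:
    rows = [dataclasses.asdict(r) for r in records]
    pd.DataFrame(rows)[_TSV_COLUMNS].to_csv(path, sep="\t", index=False)


def read_library_tsv(path: str | Path) -> list[PeptideRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"tag9": "string"})
    records = []
    for row in df.itertuples(index=False):
        records.append(
            PeptideRecord(
                peptide_id=row.peptide_id,
                source_protein=row.source_protein,
                tile_start=int(row.tile_start),
                aa_seq=row.aa_seq,
                variant_class=row.variant_class,
                sub_position=None if pd.isna(row.sub_position) else int(row.sub_position),
                nt_seq=None if pd.isna(row.nt_seq) else row.nt_seq,
                tag9=None if pd.isna(row.tag9) else row.tag9,
            )
        )
    return records


def write_library_fasta(records: Sequence[PeptideRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            if rec.nt_seq is None:
                raise ValueError(f"{rec.peptide_id} has no nt_seq")
            fh.write(f">{rec.peptide_id}\n{rec.nt_seq}\n")


def read_proteins_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}
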