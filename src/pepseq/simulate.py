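"""Ground-truthed screen simulator.

The generator mirrors the hierarchical model the inference assumes: each
peptide i has Beta(α_i, β_i) editing-rate parameters, each replicate j
realises a rate p_ij ~ Beta(α_i, β_i), and edited read counts follow
Bin(n_j, p_ij). On top of that statistical core it renders paired FASTQ
reads — read 1 carrying the peptide's nucleotide sequence, read 2 the
target amplicon — with spiked indel alleles near the nick, partial-edit
("other") alleles, per-base substitution errors with low PHRED scores at
error positions, and a two-level quality string. Every simulated cell is
recorded in a truth table so downstream counting and inference can be
checked exactly.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from pepseq.edits import EditSpec
from pepseq.library import PeptideRecord
from pepseq.reads import CountMatrix

__all__ = [
    "QualityModel",
    "draw_true_effects",
    "simulate_counts",
    "simulate_screen",
    "simulate_dual_screen",
]

TRUTH_COLUMNS = [
    "peptide_id",
    "replicate",
    "alpha",
    "beta",
    "p",
    "depth",
    "prime_edited",
    "unedited",
    "indel",
    "other",
]


@dataclass(frozen=True)
class QualityModel:
    """Two-level PHRED model: a high baseline with low scores at error sites.

    ``low_frac`` optionally marks extra random positions as low-quality to
    exercise the masking rules; it defaults to 0 so that, with no
    sequencing errors, every simulated read is classified exactly as
    planted.
    """

    high: int = 37
    low: int = 15
    low_frac: float = 0.0


def draw_true_effects(
    library: Sequence[PeptideRecord],
    control_mean: float = 0.2,
    enhancer_ids: Optional[set[str]] = None,
    enhancer_fold: float = 1.5,
    concentration: float = 100.0,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Assign Beta(α, β) editing-rate parameters to every library member.

    Non-enhancers get mean ``control_mean``; peptides in ``enhancer_ids``
    get mean ``control_mean * enhancer_fold``. All peptides share the same
    concentration α + β, which sets the replicate-to-replicate
    overdispersion. ``seed`` is accepted for interface symmetry; the
    assignment itself is deterministic.
    """
    del seed
    enhancer_ids = enhancer_ids or set()
    if concentration <= 0:
        raise ValueError("concentration must be positive")
    if not 0 < control_mean < 1:
        raise ValueError("control_mean must lie in (0, 1)")
    if control_mean * enhancer_fold >= 1:
        raise ValueError("enhancer mean would reach or exceed 1")
    effects = {}
    for rec in library:
        mean = control_mean * enhancer_fold if rec.peptide_id in enhancer_ids else control_mean
        effects[rec.peptide_id] = (mean * concentration, (1 - mean) * concentration)
    return effects


def _realized_rates(
    effects: Mapping[str, tuple[float, float]],
    replicates: Sequence[str],
    rng: np.random.Generator,
    batch_map: Optional[Mapping[str, str]],
) -> dict[tuple[str, str], float]:
    """Draw p_ij per (peptide, replicate); replicates in one batch share draws."""
    rates: dict[tuple[str, str], float] = {}
    for pid, (a, b) in effects.items():
        batch_p: dict[str, float] = {}
        for rep in replicates:
            batch = batch_map.get(rep, rep) if batch_map else rep
            if batch not in batch_p:
                batch_p[batch] = float(rng.beta(a, b))
            rates[(pid, rep)] = batch_p[batch]
    return rates


def simulate_counts(
    effects: Mapping[str, tuple[float, float]],
    depth_per_peptide: int = 1000,
    replicates: int | Sequence[str] = 3,
    indel_rate: float = 0.005,
    partial_edit_frac: float = 0.005,
    batch_map: Optional[Mapping[str, str]] = None,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate outcome counts directly at the statistical layer.

    Per cell: p_ij ~ Beta(α_i, β_i); edited ~ Bin(depth, p_ij); a fraction
    ``partial_edit_frac`` of edited reads carry only part of the programmed
    edit and are planted as ``other``; among non-edited reads a fraction
    ``indel_rate`` are planted as ``indel``. Returns the count matrix and
    the truth table (counts per cell always sum to the depth).
    """
    if depth_per_peptide < 1:
        raise ValueError("depth must be >= 1")
    for r in (indel_rate, partial_edit_frac):
        if not 0 <= r <= 1:
            raise ValueError("rates must lie in [0, 1]")
    if isinstance(replicates, int):
        replicates = [f"rep{j + 1}" for j in range(replicates)]
    rng = np.random.default_rng(seed)
    rates = _realized_rates(effects, replicates, rng, batch_map)

    rows = []
    for pid, (a, b) in effects.items():
        for rep in replicates:
            p = rates[(pid, rep)]
            edited = int(rng.binomial(depth_per_peptide, p))
            partial = int(rng.binomial(edited, partial_edit_frac))
            remaining = depth_per_peptide - edited
            indel = int(rng.binomial(remaining, indel_rate))
            rows.append(
                {
                    "peptide_id": pid,
                    "replicate": rep,
                    "alpha": a,
                    "beta": b,
                    "p": p,
                    "depth": depth_per_peptide,
                    "prime_edited": edited - partial,
                    "unedited": remaining - indel,
                    "indel": indel,
                    "other": partial,
                }
            )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)
    counts = truth[["peptide_id", "replicate", "prime_edited", "unedited", "indel", "other"]].copy()
    counts["n"] = truth["depth"]
    return CountMatrix(counts), truth


def _apply_errors(
    seq: str,
    rng: np.random.Generator,
    error_rate: float,
    qm: QualityModel,
) -> tuple[str, str]:
    """Substitution errors plus the matching quality string for one read."""
    L = len(seq)
    qual = np.full(L, qm.high, dtype=np.int32)
    if qm.low_frac > 0:
        low_pos = rng.random(L) < qm.low_frac
        qual[low_pos] = qm.low
    if error_rate > 0:
        err_pos = np.flatnonzero(rng.random(L) < error_rate)
        if err_pos.size:
            chars = list(seq)
            for pos in err_pos:
                alternatives = [b for b in "ACGT" if b != chars[pos]]
                chars[pos] = alternatives[rng.integers(0, 3)]
                qual[pos] = qm.low
            seq = "".join(chars)
    qual_str = "".join(chr(q + 33) for q in qual)
    return seq, qual_str


def _indel_read(spec: EditSpec, rng: np.random.Generator) -> str:
    """An unedited amplicon carrying a 1-3 nt indel within +-6 nt of the edit."""
    ref = spec.ref_amplicon
    length = int(rng.integers(1, 4))
    lo = max(0, spec.edit_start - 6)
    hi = min(len(ref) - length, spec.edit_end + 6)
    pos = int(rng.integers(lo, hi + 1))
    if rng.random() < 0.5:
        return ref[:pos] + ref[pos + length :]  # deletion
    ins = "".join("ACGT"[i] for i in rng.integers(0, 4, length))
    return ref[:pos] + ins + ref[pos:]


def _partial_edit_read(spec: EditSpec, rng: np.random.Generator) -> str:
    """An amplicon carrying only a proper prefix of the programmed edit."""
    l = int(rng.integers(1, len(spec.alt_allele)))
    region = spec.alt_allele[:l] + spec.ref_allele[l:]
    return spec.ref_amplicon[: spec.edit_start] + region + spec.ref_amplicon[spec.edit_end :]


def simulate_screen(
    library: Sequence[PeptideRecord],
    effects: Mapping[str, tuple[float, float]],
    spec: EditSpec,
    out_dir: str | Path,
    depth_per_peptide: int = 500,
    replicates: int | Sequence[str] = 3,
    indel_rate: float = 0.005,
    partial_edit_frac: float = 0.005,
    error_rate: float = 0.001,
    quality_model: QualityModel = QualityModel(),
    read1_len: int = 50,
    batch_map: Optional[Mapping[str, str]] = None,
    compress: bool = False,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Render a full screen as paired FASTQ files plus a truth table.

    Read 1 is the first ``read1_len`` nt of each peptide's coding sequence;
    read 2 is the (possibly edited or indel-bearing) target amplicon.
    Substitution errors at ``error_rate`` per base hit both reads and are
    flagged with low PHRED scores. Returns the sample sheet (replicate, r1,
    r2) and the truth table. Byte-identical output for identical inputs and
    seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_id = {rec.peptide_id: rec for rec in library}
    missing = [pid for pid in effects if pid not in by_id or by_id[pid].nt_seq is None]
    if missing:
        raise ValueError(f"library members without nucleotide sequence: {missing[:5]}")

    counts, truth = simulate_counts(
        effects,
        depth_per_peptide=depth_per_peptide,
        replicates=replicates,
        indel_rate=indel_rate,
        partial_edit_frac=partial_edit_frac,
        batch_map=batch_map,
        seed=seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    suffix = ".fastq.gz" if compress else ".fastq"
    sheet_rows = []
    for rep in counts.replicates:
        r1_path = out_dir / f"{rep}_R1{suffix}"
        r2_path = out_dir / f"{rep}_R2{suffix}"
        opener = gzip.open if compress else open
        with opener(r1_path, "wt") as fh1, opener(r2_path, "wt") as fh2:
            rep_truth = truth[truth["replicate"] == rep]
            for row in rep_truth.itertuples(index=False):
                nt = by_id[row.peptide_id].nt_seq
                r1_seq = nt[:read1_len]
                serial = 0
                for category, count in (
                    ("prime_edited", row.prime_edited),
                    ("unedited", row.unedited),
                    ("indel", row.indel),
                    ("other", row.other),
                ):
                    for _ in range(count):
                        if category == "prime_edited":
                            s2 = spec.edited_amplicon
                        elif category == "unedited":
                            s2 = spec.ref_amplicon
                        elif category == "indel":
                            s2 = _indel_read(spec, rng)
                        else:
                            s2 = _partial_edit_read(spec, rng)
                        s1e, q1 = _apply_errors(r1_seq, rng, error_rate, quality_model)
                        s2e, q2 = _apply_errors(s2, rng, error_rate, quality_model)
                        name = f"{row.peptide_id}:{rep}:{serial}"
                        fh1.write(f"@{name}/1\n{s1e}\n+\n{q1}\n")
                        fh2.write(f"@{name}/2\n{s2e}\n+\n{q2}\n")
                        serial += 1
        sheet_rows.append({"replicate": rep, "r1": str(r1_path), "r2": str(r2_path)})
    return pd.DataFrame(sheet_rows), truth


def simulate_dual_screen(
    effect_a: Mapping[str, float],
    effect_b: Mapping[str, float],
    baseline: float = 1.0,
    noise_sd: float = 0.05,
    replicates: int = 3,
    interaction: Optional[Callable[[str, str], float]] = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, dict]:
    """Simulate a dual-peptide grid of control-normalised editing values.

    Every (N-terminal, C-terminal) pair from the two effect maps is
    observed in each replicate as baseline + a_i + b_j (+ an optional
    interaction term) + Gaussian noise. A 10x10 input yields 100 pairs.
    """
    if not effect_a or not effect_b:
        raise ValueError("both effect maps must be non-empty")
    rng = np.random.default_rng(seed)
    rows = []
    for i, a in effect_a.items():
        for j, b in effect_b.items():
            mu = baseline + a + b
            if interaction is not None:
                mu += interaction(i, j)
            for r in range(replicates):
                rows.append(
                    {
                        "n_term_id": i,
                        "c_term_id": j,
                        "replicate": f"rep{r + 1}",
                        "normalized_edited_fraction": mu + rng.normal(0, noise_sd)
                        if noise_sd > 0
                        else mu,
                    }
                )
    truth = {"baseline": baseline, "n_effects": dict(effect_a), "c_effects": dict(effect_b)}
    return pd.DataFrame(rows), truth
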