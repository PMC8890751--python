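"""Protein alignments: FASTA I/O and column/row filtering.

The alignment container is a thin wrapper around a ``numpy`` character
matrix (taxa x sites) over the 20 amino-acid one-letter codes plus ``-``
(gap) and ``X`` (missing/ambiguous).  Both ``-`` and ``X`` are treated as
missing data by the likelihood machinery; they differ only for
gap-fraction bookkeeping, where ``-`` counts as a gap and ``X`` does not.

Filtering implements the two protocol rules used for the expanded marker
set — drop sites with >90% gaps, then drop sequences with >66% gaps
(both strictly greater-than) — plus a simplified entropy-based trimmer
standing in for BMGE (see :func:`trim_entropy`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
MISSING = "X"
#: index of each of the 22 recognised characters in likelihood state space
AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}


class AlignmentError(ValueError):
    """Raised for malformed or degenerate alignments."""


@dataclass
class Alignment:
    """An aligned set of protein sequences.

    Parameters
    ----------
    taxa
        Ordered, unique taxon identifiers.
    data
        ``(n_taxa, n_sites)`` array of single characters (dtype ``<U1``).
    source_name
        Free-text provenance label.
    site_provenance
        1-based column indices into the alignment this one was derived
        from by trimming; ``None`` for a pristine alignment.
    """

    taxa: list[str]
    data: np.ndarray
    source_name: str = ""
    site_provenance: list[int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype="<U1")
        if self.data.ndim != 2:
            raise AlignmentError("alignment data must be 2-D (taxa x sites)")
        if len(self.taxa) != self.data.shape[0]:
            raise AlignmentError(
                f"{len(self.taxa)} taxa but {self.data.shape[0]} rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise AlignmentError("duplicate taxon ids")
        if self.n_sites < 1:
            raise AlignmentError("alignment has no sites")

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence(self, taxon: str) -> str:
        return "".join(self.data[self.taxa.index(taxon)])

    def take_sites(self, idx: np.ndarray, source_name: str | None = None) -> "Alignment":
        """Column subset, tracking 1-based provenance indices."""
        idx = np.asarray(idx, dtype=int)
        base = self.site_provenance or list(range(1, self.n_sites + 1))
        return Alignment(
            list(self.taxa),
            self.data[:, idx],
            source_name=source_name or self.source_name,
            site_provenance=[base[i] for i in idx],
        )

    def take_taxa(self, keep: list[str]) -> "Alignment":
        rows = [self.taxa.index(t) for t in keep]
        return Alignment(
            list(keep), self.data[rows, :],
            source_name=self.source_name,
            site_provenance=list(self.site_provenance) if self.site_provenance else None,
        )

    def gap_matrix(self) -> np.ndarray:
        """Boolean matrix marking gap *or* missing cells ('-' or 'X')."""
        return (self.data == GAP) | (self.data == MISSING)


def _clean(seq: str) -> str:
    out = []
    for ch in seq.upper():
        if ch in AA_INDEX or ch == GAP:
            out.append(ch)
        else:
            out.append(MISSING)
    return "".join(out)


def read_fasta(path) -> Alignment:
    """Read an aligned protein FASTA file.

    States are uppercased; any character outside the 20 amino-acid codes
    (``B``, ``Z``, ``*``, ``?`` ...) becomes ``X``.  Record order is
    preserved.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"no records in {path}")
    taxa, rows = [], []
    length = None
    for rec in records:
        seq = _clean(str(rec.seq))
        if length is None:
            length = len(seq)
        elif len(seq) != length:
            raise AlignmentError(
                f"ragged alignment: record '{rec.id}' has length "
                f"{len(seq)}, expected {length}"
            )
        if rec.id in taxa:
            raise AlignmentError(f"duplicate record id '{rec.id}'")
        taxa.append(rec.id)
        rows.append(list(seq))
    if length == 0:
        raise AlignmentError("zero-length sequences")
    return Alignment(taxa, np.array(rows, dtype="<U1"), source_name=str(path))


def write_fasta(alignment: Alignment, path, width: int = 60) -> None:
    """Write FASTA with fixed-width line wrapping (round-trips exactly)."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, taxon in enumerate(alignment.taxa):
            fh.write(f">{taxon}\n")
            seq = "".join(alignment.data[i])
            for j in range(0, len(seq), width):
                fh.write(seq[j:j + width] + "\n")


def trim_gap_sites(alignment: Alignment, max_gap_fraction: float = 0.90) -> Alignment:
    """Remove columns whose gap+missing fraction strictly exceeds the cutoff.

    With the default 0.90 this is the ">90% gaps" site-removal rule: a
    column at exactly 90% gaps is retained.
    """
    frac = alignment.gap_matrix().mean(axis=0)
    keep = np.flatnonzero(frac <= max_gap_fraction)
    if keep.size == 0:
        raise AlignmentError("empty alignment after trimming")
    return alignment.take_sites(keep)


def drop_gappy_sequences(alignment: Alignment, max_gap_fraction: float = 0.66) -> Alignment:
    """Remove sequences whose gap+missing fraction strictly exceeds the cutoff.

    Applied after :func:`trim_gap_sites`; the rule is strictly ``>``, so a
    row at exactly 66% gaps survives.  Errors if fewer than 4 taxa remain
    (no unrooted topology exists below that).
    """
    frac = alignment.gap_matrix().mean(axis=1)
    keep = [t for t, f in zip(alignment.taxa, frac) if f <= max_gap_fraction]
    if len(keep) < 4:
        raise AlignmentError(
            f"only {len(keep)} sequences remain after dropping gappy rows"
        )
    return alignment.take_taxa(keep)


def _blosum62_weights() -> np.ndarray:
    """Row-normalised similarity weights from BLOSUM62 (non-negative)."""
    blosum = substitution_matrices.load("BLOSUM62")
    w = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            w[i, j] = max(blosum[a][b], 0.0)
    # every residue is at least similar to itself
    np.fill_diagonal(w, np.maximum(np.diag(w), 1.0))
    return w / w.sum(axis=1, keepdims=True)


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def column_entropies(alignment: Alignment, weights: np.ndarray | None = None) -> np.ndarray:
    """Similarity-smoothed Shannon entropy per column, normalised to [0, 1].

    Each observed residue contributes its row of the row-normalised
    BLOSUM62 weight matrix, so near-synonymous residues (e.g. I/L/V)
    add less entropy than chemically disparate ones.  The score is the
    excess of the mixture entropy over the mean per-residue entropy,
    rescaled so an invariant column scores 0 and a column uniform over
    all 20 amino acids scores 1 (with identity weights this is the
    plain normalised Shannon entropy).  Gaps and ``X`` are excluded
    from the entropy and counted separately; an all-gap column gets 0.
    """
    if weights is None:
        weights = _blosum62_weights()
    row_entropy = np.array([_entropy(weights[i]) for i in range(20)])
    ent = np.zeros(alignment.n_sites)
    log_max = np.log(20.0)
    for c in range(alignment.n_sites):
        counts = np.zeros(20)
        mix = np.zeros(20)
        for ch in alignment.data[:, c]:
            i = AA_INDEX.get(ch)
            if i is not None:
                counts[i] += 1
                mix += weights[i]
        n_obs = counts.sum()
        if n_obs <= 0:
            continue
        baseline = float((counts / n_obs) @ row_entropy)
        denom = log_max - baseline
        if denom <= 1e-12:
            continue
        ent[c] = max(_entropy(mix / n_obs) - baseline, 0.0) / denom
    return ent


def trim_entropy(
    alignment: Alignment,
    entropy_cutoff: float = 0.5,
    gap_cutoff: float = 0.2,
    weights: np.ndarray | None = None,
) -> Alignment:
    """Entropy/gap-based block trimming (simplified BMGE-style filter).

    Keeps columns with smoothed entropy <= ``entropy_cutoff`` AND gap
    fraction <= ``gap_cutoff``.  This is a deterministic stand-in for
    BMGE default trimming: the per-column entropy criterion is the same
    in spirit, but BMGE's sliding-window block smoothing is deliberately
    omitted, and output metadata labels the result accordingly.
    """
    ent = column_entropies(alignment, weights)
    gapfrac = (alignment.data == GAP).mean(axis=0)
    keep = np.flatnonzero((ent <= entropy_cutoff) & (gapfrac <= gap_cutoff))
    if keep.size == 0:
        raise AlignmentError("empty alignment after entropy trimming")
    return alignment.take_sites(
        keep, source_name=alignment.source_name + " [entropy-trimmed, simplified]"
    )
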