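"""Reference-domain conservation mapping.

Globally aligns a reference ligand-binding-domain sequence to the target
receptor sequence (Needleman–Wunsch with affine gaps, EMBOSS Needle default
settings: BLOSUM62, gap open 10, gap extend 0.5, end gaps free), classifies
alignment columns as identical / conserved / mismatch / gap, and projects the
identical+conserved columns onto target structure residues to obtain the
total conserved heavy-atom count TC_a used by the pocket enrichment
statistics.

Gap costs follow the EMBOSS convention: a gap of length L costs
``gap_open + L * gap_extend``. "Conserved" means a substitution with a
strictly positive matrix score between different letters (the EMBOSS
"similar" convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Union

from Bio import Align
from Bio.Align import substitution_matrices

from .structio import ProteinSequence, ResidueId, Structure, count_atoms, extract_sequence

COLUMN_IDENTICAL = "identical"
COLUMN_CONSERVED = "conserved"
COLUMN_MISMATCH = "mismatch"
COLUMN_GAP = "gap"


class AlignmentError(ValueError):
    pass


class ProjectionError(ValueError):
    """Alignment does not match the structure-derived sequence."""


def load_matrix(matrix: Union[str, substitution_matrices.Array] = "BLOSUM62") -> substitution_matrices.Array:
    if isinstance(matrix, str):
        return substitution_matrices.load(matrix)
    return matrix


@dataclass
class PairwiseAlignment:
    """A gapped global alignment of sequences a (reference) and b (target)."""

    seq_a: ProteinSequence
    seq_b: ProteinSequence
    aligned_a: str
    aligned_b: str
    score: float
    gap_open: float
    gap_extend: float
    matrix_name: str
    column_classes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise AlignmentError("gapped strings must have equal length")
        if self.aligned_a.replace("-", "") != self.seq_a.residues:
            raise AlignmentError("aligned_a does not recover sequence a")
        if self.aligned_b.replace("-", "") != self.seq_b.residues:
            raise AlignmentError("aligned_b does not recover sequence b")
        if any(x == "-" and y == "-" for x, y in zip(self.aligned_a, self.aligned_b)):
            raise AlignmentError("column gapped on both sides")

    def __len__(self) -> int:
        return len(self.aligned_a)

    @property
    def n_identical(self) -> int:
        return sum(c == COLUMN_IDENTICAL for c in self.column_classes)

    @property
    def n_conserved(self) -> int:
        return sum(c == COLUMN_CONSERVED for c in self.column_classes)

    @property
    def percent_identity(self) -> float:
        """Identical columns over alignment length including gaps, in percent."""
        return 100.0 * self.n_identical / len(self)

    @property
    def percent_similarity(self) -> float:
        return 100.0 * (self.n_identical + self.n_conserved) / len(self)

    def format_pair(self, width: int = 60) -> str:
        """EMBOSS-pair-style text block (sequences, midline, summary)."""
        mid = {COLUMN_IDENTICAL: "|", COLUMN_CONSERVED: ":", COLUMN_MISMATCH: ".", COLUMN_GAP: " "}
        midline = "".join(mid[c] for c in self.column_classes)
        lines = [
            f"# 1: {self.seq_a.id}",
            f"# 2: {self.seq_b.id}",
            f"# Matrix: {self.matrix_name}  Gap_penalty: {self.gap_open}  Extend_penalty: {self.gap_extend}",
            f"# Length: {len(self)}  Identity: {self.n_identical}/{len(self)} ({self.percent_identity:.1f}%)"
            f"  Similarity: {self.n_identical + self.n_conserved}/{len(self)} ({self.percent_similarity:.1f}%)",
            f"# Score: {self.score:.1f}",
        ]
        for start in range(0, len(self), width):
            lines.append(self.aligned_a[start : start + width])
            lines.append(midline[start : start + width])
            lines.append(self.aligned_b[start : start + width])
            lines.append("")
        return "\n".join(lines)


@dataclass
class ConservationMap:
    """Identical/conserved target residues and their heavy-atom total TC_a."""

    target_id: str
    conserved_residues: set[ResidueId]
    tc_a: int
    residue_classes: dict[ResidueId, str] = field(default_factory=dict)


def global_align(
    a: ProteinSequence,
    b: ProteinSequence,
    matrix: Union[str, substitution_matrices.Array] = "BLOSUM62",
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    penalize_end_gaps: bool = False,
) -> PairwiseAlignment:
    """Needleman–Wunsch global alignment with affine gaps (EMBOSS defaults).

    End gaps are free unless ``penalize_end_gaps`` is set. The traceback is
    deterministic: the engine's first optimal alignment is reported.
    """
    if not a.residues or not b.residues:
        raise AlignmentError("cannot align an empty sequence")
    mat = load_matrix(matrix)
    alphabet = set(str(mat.alphabet))
    for seq in (a, b):
        bad = set(seq.residues) - alphabet
        if bad:
            raise AlignmentError(f"symbols {sorted(bad)} absent from matrix for {seq.id}")

    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = mat
    # EMBOSS convention: gap of length L costs open + L*extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    aligner.mode = "global"
    if not penalize_end_gaps:
        try:
            aligner.end_insertion_score = 0.0
            aligner.end_deletion_score = 0.0
        except AttributeError:  # biopython < 1.86 naming
            aligner.target_end_gap_score = 0.0
            aligner.query_end_gap_score = 0.0

    alignment = aligner.align(a.residues, b.residues)[0]
    aligned_a, aligned_b = alignment[0], alignment[1]
    matrix_name = matrix if isinstance(matrix, str) else "custom"
    aln = PairwiseAlignment(
        seq_a=a,
        seq_b=b,
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(alignment.score),
        gap_open=gap_open,
        gap_extend=gap_extend,
        matrix_name=matrix_name,
    )
    aln.column_classes = classify_columns(aln, mat)
    return aln


def classify_columns(
    aln: PairwiseAlignment,
    matrix: Union[str, substitution_matrices.Array] = "BLOSUM62",
) -> list[str]:
    """Label each column identical / conserved / mismatch / gap.

    identical: same letter on both sides; conserved: different letters with a
    strictly positive substitution score; gap: either side gapped.
    """
    mat = load_matrix(matrix)
    classes = []
    for x, y in zip(aln.aligned_a, aln.aligned_b):
        if x == "-" or y == "-":
            classes.append(COLUMN_GAP)
        elif x == y:
            classes.append(COLUMN_IDENTICAL)
        elif mat[x, y] > 0:
            classes.append(COLUMN_CONSERVED)
        else:
            classes.append(COLUMN_MISMATCH)
    return classes


def build_conservation_map(
    aln: PairwiseAlignment,
    target: Structure,
    target_chain: str,
    target_side: str = "b",
) -> ConservationMap:
    """Project identical/conserved columns onto target residues; compute TC_a.

    The ungapped target side of the alignment must equal the structure-derived
    chain sequence; the first discordant position is reported otherwise.
    """
    if target_side not in ("a", "b"):
        raise ValueError("target_side must be 'a' or 'b'")
    gapped = aln.aligned_b if target_side == "b" else aln.aligned_a
    struct_seq = extract_sequence(target, target_chain)
    ungapped = gapped.replace("-", "")
    if ungapped != struct_seq.residues:
        n = min(len(ungapped), len(struct_seq.residues))
        pos = next(
            (i for i in range(n) if ungapped[i] != struct_seq.residues[i]), n
        )
        raise ProjectionError(
            f"alignment/structure sequence mismatch at target position {pos + 1} "
            f"(alignment {ungapped[pos:pos + 1]!r} vs structure "
            f"{struct_seq.residues[pos:pos + 1]!r})"
        )

    conserved: set[ResidueId] = set()
    residue_classes: dict[ResidueId, str] = {}
    pos = 0
    for col, cls in zip(gapped, aln.column_classes):
        if col == "-":
            continue
        rid = struct_seq.numbering[pos]
        residue_classes[rid] = cls
        if cls in (COLUMN_IDENTICAL, COLUMN_CONSERVED):
            conserved.add(rid)
        pos += 1
    tc_a = count_atoms(target, conserved) if conserved else 0
    return ConservationMap(
        target_id=struct_seq.id,
        conserved_residues=conserved,
        tc_a=tc_a,
        residue_classes=residue_classes,
    )
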