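"""Synthetic genomes, annotations, promoters and expression series with truth.

The generator emulates the structure of a tandemly expanded single-exon
transcription-factor clade: one chromosome carries ``n_members`` paralogs
whose ~280-residue proteins share an ordered set of conserved amino-acid
motifs, each gene preceded (in transcription orientation) by a 3000-nt
promoter carrying known counts of planted IUPAC cis-elements and nothing
else matching those patterns.  Only ``n_annotated`` members appear in the
GFF3; the rest are the "unannotated" paralogs the scan stage must find.
Expression series plant one co-expression module (the family plus a few
extra genes) against an independent background.

Divergence model: motif residues mutate at the per-member substitution
rate; inter-motif linker residues are redrawn uniformly whenever the rate is
positive, mirroring the empirical pattern that inter-motif regions of such
clades are far more variable than the motifs.  At rate 0 every member's
translation is identical.

Everything is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_core import GeneAnnotation, reverse_complement
from .promoter_census import iupac_regex

__all__ = [
    "PlantedElement",
    "FamilySpec",
    "SyntheticTruth",
    "default_motif_templates",
    "generate_family_genome",
    "generate_expression_series",
    "ExpressionTruth",
]

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"

# sense codons per residue (no stop codons, so proteins translate cleanly)
_SENSE_CODONS: dict[str, list[str]] = {}
from .paralog_scan import _CODON_TABLE  # noqa: E402  (single codon-table source)

for _codon, _aa in _CODON_TABLE.items():
    if _aa != "*":
        _SENSE_CODONS.setdefault(_aa, []).append(_codon)


@dataclass(frozen=True)
class PlantedElement:
    """A cis-element planted into every promoter at a fixed count."""

    name: str
    iupac: str
    count: int


def default_motif_templates(n: int = 9, seed: int = 2020) -> list[str]:
    """Deterministic default motif consensus templates.

    Widths span 50 down to 7 residues (the documented extremes for this kind
    of motif set) with a gently decreasing profile; residues are drawn
    uniformly from a fixed-seed generator so the defaults are constants.
    """
    widths = [50, 35, 30, 28, 25, 22, 18, 12, 7][:n]
    if n > 9:
        widths = widths + [15] * (n - 9)
    rng = np.random.default_rng(seed)
    return [
        "".join(rng.choice(list(RESIDUES), size=w)) for w in widths
    ]


@dataclass(frozen=True)
class FamilySpec:
    """Architecture of the synthetic gene family.

    Defaults mirror the real clade being emulated: 18 members of which 12
    are annotated (6 to be discovered), ~280-residue single-exon proteins
    with 9 ordered motifs, two members truncated at the N-terminus (missing
    their first 4 motifs), a third of members on the minus strand, and a few
    common plant promoter elements planted at fixed per-promoter counts.
    """

    n_members: int = 18
    member_length: int = 280
    motif_templates: tuple[str, ...] = tuple(default_motif_templates())
    substitution_rate: float = 0.05
    truncation_flags: Mapping[int, tuple[int, int]] = field(
        default_factory=lambda: {11: (4, 0), 13: (4, 0)}
    )
    intergenic_gap: int = 400
    strand_pattern: tuple[str, ...] | None = None
    n_annotated: int = 12
    promoter_length: int = 3000
    promoter_plant: tuple[PlantedElement, ...] = (
        PlantedElement("CAATBOX1", "CAAT", 5),
        PlantedElement("DOFCOREZM", "AAAG", 4),
        PlantedElement("GATABOX", "GATA", 3),
    )
    chrom_name: str = "chr16"

    def __post_init__(self) -> None:
        if self.n_annotated > self.n_members:
            raise ValueError("n_annotated cannot exceed n_members")
        if not (0.0 <= self.substitution_rate <= 0.5):
            raise ValueError("substitution rate must be in [0, 0.5]")
        for tpl in self.motif_templates:
            if not set(tpl) <= set(RESIDUES):
                raise ValueError(f"invalid residues in motif template {tpl!r}")
            if not (7 <= len(tpl) <= 50):
                raise ValueError("motif template lengths must be in [7, 50]")
        for idx, (lead, trail) in dict(self.truncation_flags).items():
            if lead + trail >= len(self.motif_templates):
                raise ValueError(f"member {idx}: truncation removes all motifs")

    def strands(self) -> list[str]:
        if self.strand_pattern is not None:
            if len(self.strand_pattern) != self.n_members:
                raise ValueError("strand_pattern length must equal n_members")
            return list(self.strand_pattern)
        # default: every third member on the minus strand (6 of 18)
        return ["-" if (i + 1) % 3 == 0 else "+" for i in range(self.n_members)]


@dataclass
class SyntheticTruth:
    """Ground truth consistent with the emitted FASTA/GFF3."""

    genes: list[GeneAnnotation]  # every member, annotated or not
    annotated_ids: set[str]
    proteins: dict[str, str]
    architectures: dict[str, list[int]]  # member -> planted template indices
    promoter_counts: dict[str, dict[str, int]]  # member -> element name -> count
    promoter_sequences: dict[str, str]  # transcription-oriented
    motif_spans: dict[str, list[tuple[int, int, int]]]  # member -> (tpl, start, end)

    @property
    def member_ids(self) -> list[str]:
        return [g.gene_id for g in self.genes]

    @property
    def novel_ids(self) -> set[str]:
        return set(self.member_ids) - self.annotated_ids

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.genes:
            rows.append(
                {
                    "gene_id": g.gene_id,
                    "seq_id": g.seq_id,
                    "start": g.start,
                    "end": g.end,
                    "strand": g.strand,
                    "annotated": g.gene_id in self.annotated_ids,
                    "motifs": ",".join(map(str, self.architectures[g.gene_id])),
                }
            )
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Protein and DNA construction


def _ancestor_layout(spec: FamilySpec) -> list[tuple[str, int]]:
    """Segments of the ancestral protein as (kind, length); kind is
    'linker' or the template index as a string."""
    total_motifs = sum(len(t) for t in spec.motif_templates)
    n_gaps = len(spec.motif_templates) + 1
    filler = spec.member_length - total_motifs
    if filler < n_gaps:
        raise ValueError(
            "member_length too short for the motif templates plus linkers"
        )
    base = filler // n_gaps
    extra = filler % n_gaps
    segments: list[tuple[str, int]] = []
    for i, tpl in enumerate(spec.motif_templates):
        gap_len = base + (1 if i < extra else 0)
        segments.append(("linker", gap_len))
        segments.append((str(i), len(tpl)))
    segments.append(("linker", base))
    return segments


def _member_protein(
    spec: FamilySpec,
    ancestor_linkers: list[str],
    member_index: int,
    rng: np.random.Generator,
) -> tuple[str, list[int], list[tuple[int, int, int]]]:
    """One member's protein, its present template indices and motif spans."""
    lead_cut, trail_cut = dict(spec.truncation_flags).get(member_index, (0, 0))
    n_motifs = len(spec.motif_templates)
    present = list(range(lead_cut, n_motifs - trail_cut))
    rate = spec.substitution_rate

    def mutate(seq: str, seq_rate: float) -> str:
        if seq_rate <= 0:
            return seq
        chars = list(seq)
        hit = rng.random(len(chars)) < seq_rate
        for k in np.flatnonzero(hit):
            alternatives = RESIDUES.replace(chars[k], "")
            chars[k] = alternatives[rng.integers(len(alternatives))]
        return "".join(chars)

    pieces: list[str] = []
    spans: list[tuple[int, int, int]] = []
    pos = 0
    for seg_idx, tpl_idx in enumerate(present):
        linker = ancestor_linkers[tpl_idx]
        if rate > 0:
            linker = "".join(rng.choice(list(RESIDUES), size=len(linker)))
        pieces.append(linker)
        pos += len(linker)
        motif = mutate(spec.motif_templates[tpl_idx], rate)
        spans.append((tpl_idx, pos, pos + len(motif)))
        pieces.append(motif)
        pos += len(motif)
    tail = ancestor_linkers[-1]
    if rate > 0:
        tail = "".join(rng.choice(list(RESIDUES), size=len(tail)))
    pieces.append(tail)
    return "".join(pieces), present, spans


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    codons = [
        _SENSE_CODONS[aa][rng.integers(len(_SENSE_CODONS[aa]))] for aa in protein
    ]
    return "".join(codons)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


# ---------------------------------------------------------------------------
# Promoter construction with exact planted element counts


def _build_promoter(
    spec: FamilySpec, rng: np.random.Generator, max_retries: int = 60
) -> tuple[str, dict[str, int]]:
    """A promoter whose forward strand contains exactly the planted counts.

    Random background positions matching any planted pattern are re-drawn
    (iterative repair) so the only matches are the planted instances.
    """
    length = spec.promoter_length
    patterns = [(el.name, iupac_regex(el.iupac), el.iupac, el.count) for el in spec.promoter_plant]
    for _ in range(max_retries):
        seq = list(_random_dna(length, rng))
        # choose non-overlapping planting intervals
        planted: list[tuple[str, int, int]] = []  # (name, start, end)
        taken: list[tuple[int, int]] = []
        ok = True
        for el in spec.promoter_plant:
            w = len(el.iupac)
            placed = 0
            for _attempt in range(400):
                if placed == el.count:
                    break
                start = int(rng.integers(0, length - w + 1))
                if any(start < e + 1 and s - 1 < start + w for s, e in taken):
                    continue
                taken.append((start, start + w))
                planted.append((el.name, start, start + w))
                placed += 1
            if placed < el.count:
                ok = False
                break
        if not ok:
            continue
        # instantiate the IUPAC patterns at their planted positions
        from .promoter_census import IUPAC_CODES

        for name, start, end in planted:
            iupac = next(el.iupac for el in spec.promoter_plant if el.name == name)
            for k, code in enumerate(iupac):
                choices = IUPAC_CODES[code]
                seq[start + k] = choices[rng.integers(len(choices))]
        planted_positions = {
            (name, start) for name, start, _ in planted
        }
        # iterative repair: redraw non-planted positions of spurious matches
        protected = np.zeros(length, dtype=bool)
        for _, start, end in planted:
            protected[start:end] = True
        repaired = False
        for _round in range(300):
            text = "".join(seq)
            spurious: list[tuple[int, int]] = []
            for name, regex, iupac, _count in patterns:
                for m in regex.finditer(text):
                    if (name, m.start(1)) not in planted_positions:
                        spurious.append((m.start(1), m.start(1) + len(iupac)))
            if not spurious:
                repaired = True
                break
            fixed_any = False
            for start, end in spurious:
                free = [k for k in range(start, end) if not protected[k]]
                if not free:
                    continue
                for k in free:
                    seq[k] = "ACGT"[rng.integers(4)]
                fixed_any = True
            if not fixed_any:
                break
        if not repaired:
            continue
        # final exact verification
        text = "".join(seq)
        counts = {}
        good = True
        for name, regex, iupac, want in patterns:
            got = sum(1 for _ in regex.finditer(text))
            counts[name] = got
            if got != want:
                good = False
        if good:
            return text, counts
    raise RuntimeError(
        "could not plant promoter elements at exact counts; "
        "use a longer intergenic gap / promoter or fewer planted elements"
    )


# ---------------------------------------------------------------------------
# Genome assembly


def generate_family_genome(
    spec: FamilySpec | None = None, seed: int = 0
) -> tuple[dict[str, str], list[GeneAnnotation], SyntheticTruth]:
    """One chromosome carrying the planted family, its annotations and truth.

    Returns ``(genome, annotations, truth)`` where ``annotations`` contains
    only the ``n_annotated`` members (the GFF3 view) and ``truth`` records
    every member.
    """
    if spec is None:
        spec = FamilySpec()
    rng = np.random.default_rng(seed)
    layout = _ancestor_layout(spec)
    linker_lengths = [ln for kind, ln in layout if kind == "linker"]
    ancestor_linkers = [
        "".join(rng.choice(list(RESIDUES), size=ln)) for ln in linker_lengths
    ]
    strands = spec.strands()

    chrom_parts: list[str] = []
    pos = 0

    def append(part: str) -> tuple[int, int]:
        nonlocal pos
        chrom_parts.append(part)
        start = pos
        pos += len(part)
        return start, pos

    genes: list[GeneAnnotation] = []
    proteins: dict[str, str] = {}
    architectures: dict[str, list[int]] = {}
    motif_spans: dict[str, list[tuple[int, int, int]]] = {}
    promoter_counts: dict[str, dict[str, int]] = {}
    promoter_sequences: dict[str, str] = {}

    append(_random_dna(spec.intergenic_gap, rng))
    for idx in range(spec.n_members):
        member_id = f"member{idx + 1:02d}"
        strand = strands[idx]
        protein, present, spans = _member_protein(spec, ancestor_linkers, idx, rng)
        gene_dna = _reverse_translate(protein, rng) + "TAA"
        promoter, counts = _build_promoter(spec, rng)
        if strand == "+":
            append(promoter)
            g_start, g_end = append(gene_dna)
        else:
            g_start, g_end = append(reverse_complement(gene_dna))
            append(reverse_complement(promoter))
        genes.append(GeneAnnotation(member_id, spec.chrom_name, g_start, g_end, strand))
        proteins[member_id] = protein
        architectures[member_id] = present
        motif_spans[member_id] = spans
        promoter_counts[member_id] = counts
        promoter_sequences[member_id] = promoter
        append(_random_dna(spec.intergenic_gap, rng))

    genome = {spec.chrom_name: "".join(chrom_parts)}
    annotated_ids = {g.gene_id for g in genes[: spec.n_annotated]}
    annotations = [g for g in genes if g.gene_id in annotated_ids]
    truth = SyntheticTruth(
        genes=genes,
        annotated_ids=annotated_ids,
        proteins=proteins,
        architectures=architectures,
        promoter_counts=promoter_counts,
        promoter_sequences=promoter_sequences,
        motif_spans=motif_spans,
    )
    return genome, annotations, truth


# ---------------------------------------------------------------------------
# Expression series with a planted co-expression module


@dataclass
class ExpressionTruth:
    """Planted module membership behind a set of expression series."""

    module_genes: list[str]
    family_genes: list[str]
    extra_genes: list[str]
    module_correlation: float


def generate_expression_series(
    module_genes: Sequence[str],
    n_series: int = 5,
    n_genes: int = 2000,
    n_samples: int = 12,
    module_correlation: float = 0.9,
    seed: int = 0,
    family_genes: Sequence[str] | None = None,
) -> tuple[list[pd.DataFrame], ExpressionTruth]:
    """Expression matrices with one planted co-expression module.

    In every series, module genes share a latent per-sample profile:
    on the log2 scale each module gene is ``sqrt(rho) * z + sqrt(1-rho) * e``
    so the expected pairwise correlation within the module is
    ``module_correlation``; background genes are independent noise.  Values
    are exponentiated to a TPM-like non-negative scale.
    """
    if not (0.0 < module_correlation < 1.0):
        raise ValueError("module_correlation must be in (0, 1)")
    if n_samples < 4:
        raise ValueError("need at least 4 samples per series")
    module_genes = list(module_genes)
    if len(module_genes) > n_genes:
        raise ValueError("module larger than the gene universe")
    if family_genes is None:
        family_genes = module_genes[: max(len(module_genes) - 2, 0)]
    family_genes = list(family_genes)
    extra_genes = [g for g in module_genes if g not in set(family_genes)]

    rng = np.random.default_rng(seed)
    n_background = n_genes - len(module_genes)
    background_ids = [f"bg{k + 1:05d}" for k in range(n_background)]
    gene_ids = module_genes + background_ids
    mu = rng.uniform(1.0, 6.0, size=n_genes)
    amp = 2.0  # log2-scale dynamic range of the latent signal

    series = []
    rho = module_correlation
    for s in range(n_series):
        z = rng.standard_normal(n_samples)
        data = np.empty((n_genes, n_samples))
        for gi in range(n_genes):
            eps = rng.standard_normal(n_samples)
            if gi < len(module_genes):
                signal = np.sqrt(rho) * z + np.sqrt(1.0 - rho) * eps
            else:
                signal = eps
            data[gi] = 2.0 ** (mu[gi] + amp * signal)
        frame = pd.DataFrame(
            data, index=gene_ids, columns=[f"s{s + 1}_r{r + 1}" for r in range(n_samples)]
        )
        series.append(frame)
    truth = ExpressionTruth(
        module_genes=module_genes,
        family_genes=family_genes,
        extra_genes=extra_genes,
        module_correlation=module_correlation,
    )
    return series, truth
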