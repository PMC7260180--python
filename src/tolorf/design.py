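"""Codon-aligned gene fragmentation, junction patches, constrained scrambling
and assembly of the chimeric ORF.

The design problem: take a panel of parental reporter/modifier coding
sequences and produce a single non-functional open reading frame that still
contains every parental peptide of length up to ``k_max`` — so that an animal
expressing the construct is centrally tolerant to every potential MHC class I
epitope of every parent. Three ideas make this work:

* every gene is split **on a codon boundary** into an N- and a C-half, so no
  parental protein is expressed intact, and concatenation can never create a
  novel codon (hence never a premature stop);
* the peptides destroyed by a split all straddle the split site, so re-adding
  the parental region of ``half_width`` codons on each side of the split (the
  *junction patch*; 2 x (k_max - 1) codons = 60 nt at the defaults) restores
  exactly those peptides;
* fragments and patches are shuffled under the constraint that no two
  consecutive elements come from the same parent, which prevents any two
  pieces of one protein from reconstituting a longer functional run.

A control epitope (by default HPV16 E7 49-57, RAHYNIVTF) is appended just
before the stop codon so that tolerance at the extreme C-terminus — i.e.
full-length translation — can be probed experimentally.
"""

from __future__ import annotations

import logging
import random
from collections import Counter
from dataclasses import dataclass, fields, replace
from itertools import pairwise
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .errors import (
    AdjacencyError,
    BadLengthError,
    ConfigError,
    ShuffleInfeasibleError,
    SplitOutOfRangeError,
    ValidationError,
)
from .seqio import START_CODON, STOP_CODONS, ReporterGene, translate_cds

log = logging.getLogger(__name__)

#: Fixed one-codon-per-amino-acid reverse-translation table. Any fixed choice
#: works (the design never claims codon optimality); this one uses common
#: codons and is part of the tool's stable contract so that reverse
#: translation is deterministic across versions.
REVERSE_CODON_TABLE: dict[str, str] = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}

#: Default control epitope: HPV16 E7 protein residues 49-57 (H-2Db-restricted).
DEFAULT_CONTROL_EPITOPE = "RAHYNIVTF"

ELEMENT_KINDS = ("fragment", "patch", "control_epitope", "orf")


def reverse_translate(aa: str) -> str:
    """Deterministically encode an amino-acid string with the fixed codon table.

    Section property: ``translate_cds(reverse_translate(x)) == x``.
    """
    try:
        return "".join(REVERSE_CODON_TABLE[a] for a in aa)
    except KeyError as exc:
        raise ValidationError(f"unknown amino acid {exc.args[0]!r}") from None


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fragment:
    """A codon-aligned half of a parent gene.

    ``codon_span`` is half-open in parent codon coordinates with the stop
    codon excluded; ``nt`` equals the parent CDS slice ``[3*start, 3*end)``.
    """

    parent_id: str
    half: str  # "N" or "C"
    codon_span: tuple[int, int]
    nt: str


@dataclass(frozen=True)
class Patch:
    """The split-site-spanning parental region that preserves junction epitopes.

    Spans ``[max(0, s - h), min(L, s + h))`` in parent codon coordinates for
    split codon ``s``, half-width ``h`` and protein length ``L``; hence at
    most ``6*h`` nucleotides, exactly ``6*h`` whenever ``h <= s <= L - h``.
    """

    parent_id: str
    split_codon: int
    half_width: int
    codon_span: tuple[int, int]
    nt: str


@dataclass(frozen=True)
class Element:
    """A shuffle/assembly unit: fragment, patch or the control epitope.

    All elements are codon-aligned (``len(nt) % 3 == 0``) — the invariant
    that guarantees junctions introduce no novel codons.
    """

    kind: str
    nt: str
    parent_id: str | None = None
    codon_span: tuple[int, int] | None = None
    half: str | None = None  # fragments only

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise ValidationError(f"unknown element kind {self.kind!r}")
        if len(self.nt) % 3 != 0:
            raise BadLengthError(
                f"element ({self.kind}, parent={self.parent_id}) length "
                f"{len(self.nt)} is not a multiple of 3"
            )
        if not self.nt:
            raise BadLengthError(
                f"element ({self.kind}, parent={self.parent_id}) is empty"
            )

    @classmethod
    def from_fragment(cls, frag: Fragment) -> "Element":
        return cls(
            kind="fragment",
            nt=frag.nt,
            parent_id=frag.parent_id,
            codon_span=frag.codon_span,
            half=frag.half,
        )

    @classmethod
    def from_patch(cls, patch: Patch) -> "Element":
        return cls(
            kind="patch",
            nt=patch.nt,
            parent_id=patch.parent_id,
            codon_span=patch.codon_span,
        )

    @property
    def n_codons(self) -> int:
        return len(self.nt) // 3

    @property
    def protein(self) -> str:
        return translate_cds(self.nt)


@dataclass(frozen=True)
class DesignConfig:
    """All tunable parameters of a design run.

    ``k_min``/``k_max`` bound the epitope lengths audited (8-11 aa covers MHC
    class I ligands); ``patch_half_width`` defaults to ``k_max - 1`` codons,
    which is exactly the flank needed so every k-mer straddling a split
    survives inside the patch — 60 nt of parental context at the defaults.
    """

    k_min: int = 8
    k_max: int = 11
    patch_half_width: int | None = None  # None -> k_max - 1
    seed: int | None = None  # None -> drawn from entropy, recorded in report
    split_codons: Mapping[str, int] | None = None  # parent id -> codon
    control_epitope_aa: str = DEFAULT_CONTROL_EPITOPE
    control_epitope_nt: str | None = None
    stop_codon: str = "TAA"
    max_shuffle_attempts: int = 10000
    adjacency: str = "strict"  # "strict" | "minimal"

    def __post_init__(self) -> None:
        if not (1 <= self.k_min <= self.k_max):
            raise ConfigError(
                f"require 1 <= k_min <= k_max, got ({self.k_min}, {self.k_max})"
            )
        if self.patch_half_width is not None and self.patch_half_width < 1:
            raise ConfigError("patch_half_width must be >= 1")
        if self.stop_codon not in STOP_CODONS:
            raise ConfigError(f"stop_codon must be one of {STOP_CODONS}")
        if self.adjacency not in ("strict", "minimal"):
            raise ConfigError("adjacency must be 'strict' or 'minimal'")
        if self.max_shuffle_attempts < 1:
            raise ConfigError("max_shuffle_attempts must be >= 1")
        if not self.control_epitope_aa:
            raise ConfigError("control_epitope_aa must be nonempty")
        if self.control_epitope_nt is not None:
            got = translate_cds(self.control_epitope_nt)
            if got != self.control_epitope_aa:
                raise ConfigError(
                    f"control_epitope_nt translates to {got!r}, expected "
                    f"{self.control_epitope_aa!r}"
                )

    @property
    def half_width(self) -> int:
        return (
            self.patch_half_width
            if self.patch_half_width is not None
            else self.k_max - 1
        )

    @property
    def epitope_nt(self) -> str:
        if self.control_epitope_nt is not None:
            return self.control_epitope_nt
        return reverse_translate(self.control_epitope_aa)

    def resolved(self) -> "DesignConfig":
        """Return a copy with the seed fixed (drawn from entropy if unset)."""
        if self.seed is not None:
            return self
        seed = random.SystemRandom().randrange(2**31)
        log.info("no seed given; drew %d from system entropy", seed)
        return replace(self, seed=seed)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "DesignConfig":
        """Load a config from a YAML mapping; keyword overrides win."""
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def snapshot(self) -> dict:
        """JSON-serializable snapshot for reports and manifests."""
        return {
            "k_min": self.k_min,
            "k_max": self.k_max,
            "patch_half_width": self.half_width,
            "seed": self.seed,
            "split_codons": dict(self.split_codons) if self.split_codons else None,
            "control_epitope_aa": self.control_epitope_aa,
            "control_epitope_nt": self.epitope_nt,
            "stop_codon": self.stop_codon,
            "max_shuffle_attempts": self.max_shuffle_attempts,
            "adjacency": self.adjacency,
        }


@dataclass(frozen=True)
class TolConstruct:
    """The assembled chimeric ORF.

    ``elements`` is the ordered tuple of assembled units including the
    terminal control epitope; ``junctions`` lists the protein positions
    (0-based) at which each element after the first begins. The nucleotide
    sequence is ``[ATG if needed] + elements + stop``; its codon multiset is
    exactly the union of the element codons plus that bookkeeping, so no
    junction can introduce a stop.
    """

    elements: tuple[Element, ...]
    nt: str
    protein: str
    junctions: tuple[int, ...]
    config: DesignConfig
    atg_prepended: bool

    def feature_table(self) -> list[dict]:
        """Per-element construct coordinates (0-based half-open, tiling).

        Includes a ``start_codon`` row when an ATG was prepended and always a
        terminal ``stop_codon`` row; consecutive rows tile ``[0, len(nt))``.
        """
        rows: list[dict] = []
        off = 0
        if self.atg_prepended:
            rows.append(
                {"kind": "start_codon", "parent_id": None, "parent_span": None,
                 "half": None, "start": 0, "end": 3}
            )
            off = 3
        for el in self.elements:
            rows.append(
                {"kind": el.kind, "parent_id": el.parent_id,
                 "parent_span": el.codon_span, "half": el.half,
                 "start": off, "end": off + len(el.nt)}
            )
            off += len(el.nt)
        rows.append(
            {"kind": "stop_codon", "parent_id": None, "parent_span": None,
             "half": None, "start": off, "end": off + 3}
        )
        return rows

    def codon_multiset(self) -> Counter:
        return Counter(self.nt[i:i + 3] for i in range(0, len(self.nt), 3))


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def split_gene(
    gene: ReporterGene, split_codon: int | None = None
) -> tuple[Fragment, Fragment]:
    """Split a gene on a codon boundary into N- and C-half fragments.

    The stop codon is stripped; the two fragments tile the remaining CDS.
    Default split is the protein midpoint ``floor(L / 2)``, which disrupts
    function symmetrically; any ``1 <= split_codon <= L - 1`` is accepted.
    """
    L = gene.protein_length
    s = L // 2 if split_codon is None else split_codon
    if not 1 <= s <= L - 1:
        raise SplitOutOfRangeError(
            f"gene {gene.id}: split codon {s} outside [1, {L - 1}]"
        )
    body = gene.cds[: 3 * L]
    n_half = Fragment(gene.id, "N", (0, s), body[: 3 * s])
    c_half = Fragment(gene.id, "C", (s, L), body[3 * s:])
    return n_half, c_half


def make_patch(
    gene: ReporterGene, split_codon: int, half_width: int
) -> Patch:
    """Extract the parental region of ``half_width`` codons flanking a split.

    Near a gene terminus the span is clamped to the protein; the missing
    flank does not exist in the parent either, so truncation never loses a
    parental peptide (it is logged, not fatal). A full-width patch is
    ``6 * half_width`` nucleotides — 60 nt at the default ``half_width`` 10.
    """
    L = gene.protein_length
    if not 1 <= split_codon <= L - 1:
        raise SplitOutOfRangeError(
            f"gene {gene.id}: split codon {split_codon} outside [1, {L - 1}]"
        )
    if half_width < 1:
        raise ConfigError("half_width must be >= 1")
    lo = max(0, split_codon - half_width)
    hi = min(L, split_codon + half_width)
    if hi - lo < 2 * half_width:
        log.info(
            "gene %s: patch truncated to [%d, %d) at gene terminus",
            gene.id, lo, hi,
        )
    return Patch(
        parent_id=gene.id,
        split_codon=split_codon,
        half_width=half_width,
        codon_span=(lo, hi),
        nt=gene.cds[3 * lo: 3 * hi],
    )


def _adjacency_ok(order: Sequence[Element], mode: str) -> bool:
    for a, b in pairwise(order):
        if mode == "strict":
            if a.parent_id is not None and a.parent_id == b.parent_id:
                return False
        else:  # minimal: a gene's N-half must not directly precede its C-half
            if (
                a.kind == "fragment" and b.kind == "fragment"
                and a.parent_id == b.parent_id
                and a.half == "N" and b.half == "C"
            ):
                return False
    return True


def constrained_shuffle(
    elements: Sequence[Element],
    seed: int,
    max_attempts: int = 10000,
    adjacency: str = "strict",
) -> list[Element]:
    """Seeded uniform shuffle, rejected until the adjacency constraint holds.

    Under the default ``strict`` mode no two consecutive elements may share a
    parent; rejection sampling keeps the distribution uniform over valid
    permutations. Infeasibility is raised immediately when provable by
    pigeonhole (one parent owning more than ``ceil(n / 2)`` elements forces
    an adjacent same-parent pair in every permutation), otherwise after
    ``max_attempts`` rejections.
    """
    order = list(elements)
    n = len(order)
    if n == 0:
        raise ValidationError("no elements to shuffle")
    if adjacency == "strict":
        counts = Counter(e.parent_id for e in order if e.parent_id is not None)
        if counts:
            worst, cmax = counts.most_common(1)[0]
            if cmax > (n + 1) // 2:
                raise ShuffleInfeasibleError(
                    f"parent {worst} owns {cmax} of {n} elements; "
                    f"no adjacency-free permutation exists"
                )
    rng = random.Random(seed)
    for attempt in range(1, max_attempts + 1):
        rng.shuffle(order)
        if _adjacency_ok(order, adjacency):
            log.debug("valid order found after %d attempt(s)", attempt)
            return order
    raise ShuffleInfeasibleError(
        f"no valid permutation found in {max_attempts} attempts"
    )


def assemble(ordering: Sequence[Element], config: DesignConfig) -> TolConstruct:
    """Concatenate ordered elements into a single translatable ORF.

    Appends the control epitope (always last — C-terminal placement lets
    full-length translation be probed) and the configured stop codon, and
    prepends an ATG only when the first element does not already begin with
    one. Codon alignment of every element guarantees the resulting protein
    contains no stop; that is asserted, not handled.
    """
    ordering = list(ordering)
    if not ordering:
        raise ValidationError("cannot assemble an empty element list")
    if not _adjacency_ok(ordering, config.adjacency):
        raise AdjacencyError(
            "ordering violates the same-parent adjacency constraint"
        )
    epitope = Element(kind="control_epitope", nt=config.epitope_nt)
    elements = tuple(ordering) + (epitope,)

    atg_prepended = not elements[0].nt.startswith(START_CODON)
    parts = [START_CODON] if atg_prepended else []
    # a prepended start codon creates a boundary of its own; record it so the
    # junctional-peptide audit can attribute novelties arising there
    junctions = [1] if atg_prepended else []
    codon_off = 1 if atg_prepended else 0
    for i, el in enumerate(elements):
        if i > 0:
            junctions.append(codon_off)
        parts.append(el.nt)
        codon_off += el.n_codons
    parts.append(config.stop_codon)
    nt = "".join(parts)

    protein = translate_cds(nt, strip_terminal_stop=True)
    assert "*" not in protein, "junction stop codon — codon alignment violated"
    construct = TolConstruct(
        elements=elements,
        nt=nt,
        protein=protein,
        junctions=tuple(junctions),
        config=config,
        atg_prepended=atg_prepended,
    )
    assert construct.protein.endswith(config.control_epitope_aa)
    return construct


@dataclass
class DesignReport:
    """Run metadata plus the ordered element table of a finished design."""

    seed: int
    tool_version: str
    split_codons: dict[str, int]
    n_genes: int
    construct_length_nt: int
    protein_length_aa: int
    elements: list[dict]  # index, kind, parent, parent_span, nt_length

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.elements)

    def to_tsv(self, path: str | Path) -> Path:
        path = Path(path)
        with open(path, "w") as fh:
            fh.write(f"# tool_version\t{self.tool_version}\n")
            fh.write(f"# seed\t{self.seed}\n")
            fh.write(f"# n_genes\t{self.n_genes}\n")
            fh.write(f"# construct_length_nt\t{self.construct_length_nt}\n")
            fh.write(f"# protein_length_aa\t{self.protein_length_aa}\n")
            splits = ",".join(
                f"{k}:{v}" for k, v in sorted(self.split_codons.items())
            )
            fh.write(f"# split_codons\t{splits}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False)
        return path


def design(
    genes: Sequence[ReporterGene], config: DesignConfig
) -> tuple[TolConstruct, "CoverageReport", DesignReport]:
    """End-to-end pipeline: split, patch, shuffle, assemble, audit.

    Requires at least two genes (the strict adjacency constraint cannot be
    satisfied by a single parent's three elements). With the default
    ``patch_half_width = k_max - 1`` the returned coverage report is complete:
    every parental k-mer for ``k_min <= k <= k_max`` occurs in the construct
    protein.
    """
    from .audit import verify_epitope_coverage

    if len(genes) < 2:
        raise ValidationError(
            f"need >= 2 genes for a scrambled design, got {len(genes)}"
        )
    ids = [g.id for g in genes]
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate gene ids in design input")
    config = config.resolved()

    splits: dict[str, int] = {}
    elements: list[Element] = []
    for gene in genes:
        s = None
        if config.split_codons and gene.id in config.split_codons:
            s = config.split_codons[gene.id]
        n_half, c_half = split_gene(gene, s)
        s_used = n_half.codon_span[1]
        splits[gene.id] = s_used
        patch = make_patch(gene, s_used, config.half_width)
        elements.extend(
            [Element.from_fragment(n_half), Element.from_fragment(c_half),
             Element.from_patch(patch)]
        )

    ordering = constrained_shuffle(
        elements,
        seed=config.seed,
        max_attempts=config.max_shuffle_attempts,
        adjacency=config.adjacency,
    )
    construct = assemble(ordering, config)
    coverage = verify_epitope_coverage(
        genes, construct, config.k_min, config.k_max
    )
    report = DesignReport(
        seed=config.seed,
        tool_version=__version__,
        split_codons=splits,
        n_genes=len(genes),
        construct_length_nt=len(construct.nt),
        protein_length_aa=len(construct.protein),
        elements=[
            {
                "index": i,
                "kind": row["kind"],
                "parent": row["parent_id"] or "NA",
                "parent_span": (
                    "NA" if row["parent_span"] is None
                    else f"{row['parent_span'][0]}-{row['parent_span'][1]}"
                ),
                "nt_length": row["end"] - row["start"],
            }
            for i, row in enumerate(construct.feature_table())
        ],
    )
    return construct, coverage, report
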