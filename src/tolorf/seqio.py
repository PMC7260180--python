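"""Reading, validating and serializing coding sequences and assembled constructs.

The tool works exclusively on complete, in-frame open reading frames: a start
codon, a run of sense codons, and exactly one terminal stop codon. Validation
is strict and deterministic — IUPAC ambiguity codes are rejected rather than
translated, because the downstream design must be reproducible at nucleotide
level. Internal coordinates are 0-based half-open throughout; only the GFF3 /
GenBank writers convert to the 1-based inclusive convention of those formats.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import cached_property
from pathlib import Path
from typing import TYPE_CHECKING

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import (
    BadLengthError,
    DuplicateIdError,
    InputNotFoundError,
    InternalStopError,
    MissingStartError,
    MissingStopError,
    NonAcgtError,
    ValidationError,
)

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .design import TolConstruct

log = logging.getLogger(__name__)

START_CODON = "ATG"
STOP_CODONS = ("TAA", "TAG", "TGA")
_NUCLEOTIDES = frozenset("ACGT")

#: GenBank flat files require a modification date; a fixed one keeps output
#: byte-identical across runs (the run manifest records real timestamps).
_GENBANK_DATE = "01-JAN-2020"


def translate_cds(nt: str, strip_terminal_stop: bool = False) -> str:
    """Translate an in-frame nucleotide string with the standard genetic code.

    Parameters
    ----------
    nt
        Nucleotide sequence over ``{A, C, G, T}``; length must be a multiple
        of three. The empty string translates to the empty string.
    strip_terminal_stop
        If true and the final codon is a stop, it is dropped from the output;
        otherwise a stop is rendered as ``*``.
    """
    if len(nt) % 3 != 0:
        raise BadLengthError(
            f"sequence length {len(nt)} is not a multiple of 3"
        )
    bad = set(nt) - _NUCLEOTIDES
    if bad:
        raise NonAcgtError(
            f"non-ACGT characters {sorted(bad)} (ambiguity codes are rejected)"
        )
    if not nt:
        return ""
    aa = str(Seq(nt).translate())
    if strip_terminal_stop and aa.endswith("*"):
        aa = aa[:-1]
    return aa


@dataclass(frozen=True)
class ReporterGene:
    """A validated parental coding sequence.

    Invariants (enforced on construction): the CDS is over ``{A,C,G,T}``, its
    length is a multiple of 3, it begins with ``ATG``, ends with exactly one
    stop codon, and contains no internal stop. ``protein`` is the translation
    of the stop-stripped CDS and has length ``len(cds)/3 - 1``.
    """

    id: str
    cds: str
    role: str = "reporter"  # "reporter" or "modifier"

    def __post_init__(self) -> None:
        name = self.id or "<unnamed>"
        if self.role not in ("reporter", "modifier"):
            raise ValidationError(f"record {name}: unknown role {self.role!r}")
        bad = set(self.cds) - _NUCLEOTIDES
        if bad:
            raise NonAcgtError(
                f"record {name}: non-ACGT characters {sorted(bad)}"
            )
        if len(self.cds) % 3 != 0:
            raise BadLengthError(
                f"record {name}: length {len(self.cds)} not divisible by 3"
            )
        if len(self.cds) < 9:
            raise BadLengthError(
                f"record {name}: ORF must span at least start, one sense "
                f"codon and stop (9 nt); got {len(self.cds)}"
            )
        if not self.cds.startswith(START_CODON):
            raise MissingStartError(
                f"record {name}: does not begin with ATG"
            )
        if self.cds[-3:] not in STOP_CODONS:
            raise MissingStopError(
                f"record {name}: does not end with a stop codon"
            )
        body = translate_cds(self.cds[:-3])
        if "*" in body:
            raise InternalStopError(
                f"record {name}: internal stop at codon {body.index('*') + 1}"
            )

    @cached_property
    def protein(self) -> str:
        """Amino-acid sequence (terminal stop excluded)."""
        return translate_cds(self.cds[:-3])

    @property
    def protein_length(self) -> int:
        return len(self.cds) // 3 - 1


def load_reporter_genes(fasta_path: str | Path) -> list[ReporterGene]:
    """Read a multi-FASTA of parental ORFs into validated :class:`ReporterGene`s.

    Record order is preserved and ids must be unique. Lower-case sequence is
    upper-cased (common FASTA dialect), logged once per file. A record whose
    description contains the token ``role=modifier`` is loaded as a modifier
    gene; everything else is a reporter.
    """
    path = Path(fasta_path)
    if not path.is_file():
        raise InputNotFoundError(f"input file not found: {path}")
    genes: list[ReporterGene] = []
    seen: set[str] = set()
    lowercase_seen = False
    for record in SeqIO.parse(str(path), "fasta"):
        seq = str(record.seq)
        if seq != seq.upper():
            lowercase_seen = True
            seq = seq.upper()
        if record.id in seen:
            raise DuplicateIdError(f"record {record.id}: duplicate id")
        seen.add(record.id)
        role = "modifier" if "role=modifier" in record.description else "reporter"
        genes.append(ReporterGene(id=record.id, cds=seq, role=role))
    if lowercase_seen:
        log.info("%s: lower-case nucleotides upper-cased on load", path)
    if not genes:
        raise ValidationError(f"{path}: no FASTA records found")
    return genes


def write_genes(genes: list[ReporterGene], fasta_out: str | Path) -> Path:
    """Write genes back to multi-FASTA (round-trip partner of the loader)."""
    path = Path(fasta_out)
    records = []
    for g in genes:
        desc = f"role={g.role}"
        records.append(SeqRecord(Seq(g.cds), id=g.id, description=desc))
    SeqIO.write(records, str(path), "fasta")
    return path


# ---------------------------------------------------------------------------
# construct output
# ---------------------------------------------------------------------------

def _feature_label(row: dict) -> str:
    if row["kind"] == "fragment":
        return f"{row['parent_id']}_{row['half']}_fragment"
    if row["kind"] == "patch":
        return f"{row['parent_id']}_patch"
    return row["kind"]


def write_construct(
    construct: "TolConstruct",
    fasta_out: str | Path,
    genbank_out: str | Path | None = None,
    gff3_out: str | Path | None = None,
    construct_id: str = "Tol_ORF",
) -> list[Path]:
    """Serialize an assembled construct to FASTA and annotated GenBank/GFF3.

    One feature is written per construct element, plus bookkeeping features
    for the prepended start codon (when one was added) and the terminal stop,
    so consecutive feature intervals tile the ORF exactly. GFF3 coordinates
    are 1-based inclusive; slicing the FASTA with any feature interval
    reconstructs that element's sequence.
    """
    if not construct.elements:
        raise ValidationError("construct has no elements")
    written: list[Path] = []
    rows = construct.feature_table()

    fasta_path = Path(fasta_out)
    rec = SeqRecord(
        Seq(construct.nt), id=construct_id, description="chimeric scrambled ORF"
    )
    SeqIO.write([rec], str(fasta_path), "fasta")
    written.append(fasta_path)

    if genbank_out is not None:
        gb_rec = SeqRecord(
            Seq(construct.nt),
            id=construct_id,
            name=construct_id[:16],
            description="chimeric scrambled ORF",
            annotations={
                "molecule_type": "DNA",
                "topology": "linear",
                "date": _GENBANK_DATE,
            },
        )
        for row in rows:
            note = (
                f"kind={row['kind']};parent={row['parent_id'] or 'NA'};"
                f"parent_codons={_span_str(row['parent_span'])}"
            )
            gb_rec.features.append(
                SeqFeature(
                    SimpleLocation(row["start"], row["end"], strand=1),
                    type="misc_feature",
                    qualifiers={"label": [_feature_label(row)], "note": [note]},
                )
            )
        gb_path = Path(genbank_out)
        SeqIO.write([gb_rec], str(gb_path), "genbank")
        written.append(gb_path)

    if gff3_out is not None:
        gff_path = Path(gff3_out)
        with open(gff_path, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {construct_id} 1 {len(construct.nt)}\n")
            for i, row in enumerate(rows):
                attrs = (
                    f"ID={construct_id}.{i};Kind={row['kind']};"
                    f"Parent_gene={row['parent_id'] or 'NA'};"
                    f"Parent_span={_span_str(row['parent_span'])}"
                )
                fh.write(
                    "\t".join(
                        [
                            construct_id,
                            "tolorf",
                            "sequence_feature",
                            str(row["start"] + 1),  # 1-based inclusive
                            str(row["end"]),
                            ".",
                            "+",
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
        written.append(gff_path)
    return written


def _span_str(span: tuple[int, int] | None) -> str:
    return "NA" if span is None else f"{span[0]}-{span[1]}"


@dataclass(frozen=True)
class Gff3Feature:
    """One row of the GFF3 dialect this tool writes (0-based half-open)."""

    seqid: str
    start: int
    end: int
    attributes: dict[str, str] = field(hash=False)


def read_gff3_features(gff3_path: str | Path) -> list[Gff3Feature]:
    """Re-read features written by :func:`write_construct`.

    Coordinates are converted back to 0-based half-open so that
    ``fasta_sequence[f.start:f.end]`` recovers each feature's sequence.
    """
    path = Path(gff3_path)
    if not path.is_file():
        raise InputNotFoundError(f"input file not found: {path}")
    features: list[Gff3Feature] = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValidationError(f"{path}: malformed GFF3 line: {line!r}")
            attrs = dict(
                kv.split("=", 1) for kv in cols[8].split(";") if "=" in kv
            )
            features.append(
                Gff3Feature(
                    seqid=cols[0],
                    start=int(cols[3]) - 1,
                    end=int(cols[4]),
                    attributes=attrs,
                )
            )
    return features


def load_construct(fasta_path: str | Path) -> "TolConstruct":
    """Load an externally produced construct FASTA as a degenerate construct.

    The single record must be a valid ORF (start, in-frame, one terminal
    stop, no internal stops); it is wrapped as a one-element construct of
    kind ``orf`` so the audit operations can run on it.
    """
    from .design import DesignConfig, Element, TolConstruct

    path = Path(fasta_path)
    if not path.is_file():
        raise InputNotFoundError(f"input file not found: {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(
            f"{path}: expected exactly one construct record, found {len(records)}"
        )
    rec = records[0]
    nt = str(rec.seq).upper()
    # reuse ORF validation wholesale
    gene = ReporterGene(id=rec.id, cds=nt)
    element = Element(kind="orf", nt=nt[:-3], parent_id=rec.id)
    return TolConstruct(
        elements=(element,),
        nt=nt,
        protein=gene.protein,
        junctions=(),
        config=DesignConfig(seed=0),
        atg_prepended=False,
    )
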