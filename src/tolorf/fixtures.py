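"""Synthetic parental ORF generators.

Everything the test suite and documentation run on is generated here from a
seed — no downloads, no real fluorescent-protein sequences (tests must not
depend on biological sequence content; stand-in genes are labelled as
synthetic). Random codons are drawn from the 61 sense codons, so an internal
stop can never occur by construction rather than by rejection.
"""

from __future__ import annotations

import logging
import random
from dataclasses import dataclass
from itertools import product

from .errors import ConfigError
from .seqio import STOP_CODONS, ReporterGene

log = logging.getLogger(__name__)

#: The 61 sense codons of the standard code, in fixed lexicographic order.
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(p) for p in product("ACGT", repeat=3))
    if c not in STOP_CODONS
)


@dataclass(frozen=True)
class SynthSpec:
    """Parameters of a synthetic gene panel.

    ``codons_per_gene`` is the protein length of each gene (an int applied to
    all, or one value per gene); the emitted CDS is 3 codons longer (start is
    included in the count, stop is appended). ``gc_bias`` optionally reweights
    codon draws toward the given GC fraction.
    """

    n_genes: int = 8
    codons_per_gene: int | tuple[int, ...] = 240
    seed: int = 0
    gc_bias: float | None = None

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise ConfigError("n_genes must be >= 1")
        lens = self.lengths()
        if any(l < 2 for l in lens):
            raise ConfigError("codons_per_gene must be >= 2 for every gene")
        if any(l < 12 for l in lens):
            log.warning(
                "genes shorter than ~a dozen codons make poor design inputs "
                "(k-mer audits become trivial)"
            )
        if self.gc_bias is not None and not 0.0 <= self.gc_bias <= 1.0:
            raise ConfigError("gc_bias must lie in [0, 1]")

    def lengths(self) -> tuple[int, ...]:
        if isinstance(self.codons_per_gene, int):
            return (self.codons_per_gene,) * self.n_genes
        if len(self.codons_per_gene) != self.n_genes:
            raise ConfigError(
                f"got {len(self.codons_per_gene)} lengths for "
                f"{self.n_genes} genes"
            )
        return tuple(self.codons_per_gene)


def _codon_weights(gc_bias: float) -> list[float]:
    pg = gc_bias / 2.0
    pa = (1.0 - gc_bias) / 2.0
    weights = []
    for codon in SENSE_CODONS:
        w = 1.0
        for base in codon:
            w *= pg if base in "GC" else pa
        weights.append(w)
    return weights


def synth_reporter_orf(
    codons: int,
    seed: int,
    gene_id: str | None = None,
    role: str = "reporter",
    gc_bias: float | None = None,
) -> ReporterGene:
    """Generate one valid synthetic ORF of ``codons`` protein codons.

    The CDS is ``ATG`` + ``codons - 1`` random sense codons + one stop codon,
    so the translated protein has length exactly ``codons`` and internal
    stops are impossible. Deterministic per ``(codons, seed, gc_bias)``.
    """
    if codons < 2:
        raise ConfigError(f"codons must be >= 2, got {codons}")
    rng = random.Random(seed)
    if gc_bias is None:
        body = "".join(rng.choice(SENSE_CODONS) for _ in range(codons - 1))
    else:
        body = "".join(
            rng.choices(SENSE_CODONS, weights=_codon_weights(gc_bias),
                        k=codons - 1)
        )
    stop = rng.choice(STOP_CODONS)
    cds = "ATG" + body + stop
    return ReporterGene(
        id=gene_id or f"synth{seed}", cds=cds, role=role
    )


def synth_panel(spec: SynthSpec) -> list[ReporterGene]:
    """Generate a panel of synthetic genes from a :class:`SynthSpec`."""
    rng = random.Random(spec.seed)
    genes = []
    for i, length in enumerate(spec.lengths()):
        genes.append(
            synth_reporter_orf(
                codons=length,
                seed=rng.randrange(2**31),
                gene_id=f"g{i + 1}",
                gc_bias=spec.gc_bias,
            )
        )
    return genes


#: Protein lengths (codons) of the eight-gene panel: six fluorescent-protein-
#: sized genes (~220-240 aa), one luciferase-sized gene (~550 aa) and one
#: recombinase-sized modifier (~343 aa) — the size profile of a typical
#: seven-reporter-plus-one-modifier cassette.
TOL_SCALE_LENGTHS: tuple[int, ...] = (233, 229, 225, 218, 233, 239, 550, 343)
TOL_SCALE_IDS: tuple[str, ...] = (
    "sFP1", "sFP2", "sFP3", "sFP4", "sFP5", "sFP6", "sLUC", "sCRE"
)


def tol_scale_panel(seed: int) -> list[ReporterGene]:
    """Eight synthetic genes with a realistic reporter-panel size profile.

    Purely synthetic stand-ins (random sense codons) — the panel emulates the
    *structure* of a seven-reporter-plus-one-modifier cassette, not any real
    sequence. Designing on it with defaults yields 16 fragments + 8 patches +
    1 control epitope = 25 elements and a several-kilobase chimeric ORF.
    """
    rng = random.Random(seed)
    genes = []
    for gene_id, length in zip(TOL_SCALE_IDS, TOL_SCALE_LENGTHS):
        genes.append(
            synth_reporter_orf(
                codons=length,
                seed=rng.randrange(2**31),
                gene_id=gene_id,
                role="modifier" if gene_id == "sCRE" else "reporter",
            )
        )
    return genes
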