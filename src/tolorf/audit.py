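"""Epitope-coverage verification and peptidome audits of an assembled construct.

Coverage is judged on the amino-acid sequence: an epitope is a peptide, and a
parental k-mer counts as preserved iff it occurs as a contiguous substring of
the construct protein. Nucleotide-level identity is neither required nor
claimed. The audits are exhaustive — every parent, every k in the configured
range, every position — and deliberately simple enough to cross-check against
brute-force oracles.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from .design import TolConstruct
from .seqio import ReporterGene

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# coverage
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KCoverage:
    """Coverage of one parent's k-mers for a single k.

    ``missing`` maps each distinct missing peptide to the tuple of parent
    positions (0-based) at which it occurs — a peptide arising at several
    positions is reported once, with all sources attached.
    """

    total: int
    missing: dict[str, tuple[int, ...]]

    @property
    def n_missing_positions(self) -> int:
        return sum(len(pos) for pos in self.missing.values())

    @property
    def n_preserved(self) -> int:
        return self.total - self.n_missing_positions


@dataclass(frozen=True)
class CoverageReport:
    """Per-parent, per-k audit of preserved and missing parental peptides."""

    k_min: int
    k_max: int
    per_parent: dict[str, dict[int, KCoverage]]

    @property
    def complete(self) -> bool:
        return all(
            not cov.missing
            for by_k in self.per_parent.values()
            for cov in by_k.values()
        )

    @property
    def n_missing_total(self) -> int:
        return sum(
            cov.n_missing_positions
            for by_k in self.per_parent.values()
            for cov in by_k.values()
        )

    def rows(self) -> list[dict]:
        out = []
        for parent in self.per_parent:
            for k in range(self.k_min, self.k_max + 1):
                cov = self.per_parent[parent][k]
                out.append(
                    {
                        "parent": parent,
                        "k": k,
                        "total": cov.total,
                        "n_missing": cov.n_missing_positions,
                        "missing_peptides": ",".join(sorted(cov.missing)),
                    }
                )
        return out

    def to_tsv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        pd.DataFrame(
            self.rows(),
            columns=["parent", "k", "total", "n_missing", "missing_peptides"],
        ).to_csv(path, sep="\t", index=False)
        return path

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "k_min": self.k_min,
            "k_max": self.k_max,
            "complete": self.complete,
            "per_parent": {
                parent: {
                    str(k): {
                        "total": cov.total,
                        "n_missing": cov.n_missing_positions,
                        "missing": {
                            pep: list(pos) for pep, pos in sorted(cov.missing.items())
                        },
                    }
                    for k, cov in by_k.items()
                }
                for parent, by_k in self.per_parent.items()
            },
        }
        path.write_text(json.dumps(payload, indent=2) + "\n")
        return path


def _kmer_set(protein: str, k: int) -> set[str]:
    return {protein[i:i + k] for i in range(len(protein) - k + 1)}


def verify_epitope_coverage(
    parents: Sequence[ReporterGene],
    construct: TolConstruct,
    k_min: int,
    k_max: int,
) -> CoverageReport:
    """Check that every parental k-mer survives in the construct protein.

    For each parent and each ``k_min <= k <= k_max``, every length-k window
    of the parent protein is looked up in the construct's k-mer set; windows
    not found are reported with their parent positions. An empty parent list
    yields a trivially complete report (logged as suspicious).
    """
    if k_min > k_max:
        raise ValueError(f"k_min {k_min} > k_max {k_max}")
    if not construct.protein:
        raise ValueError("construct protein is empty")
    if not parents:
        log.warning("coverage audit called with no parents: trivially complete")
    per_parent: dict[str, dict[int, KCoverage]] = {}
    for k in range(k_min, k_max + 1):
        have = _kmer_set(construct.protein, k)
        for gene in parents:
            prot = gene.protein
            total = max(0, len(prot) - k + 1)
            missing: dict[str, list[int]] = {}
            for i in range(total):
                pep = prot[i:i + k]
                if pep not in have:
                    missing.setdefault(pep, []).append(i)
            per_parent.setdefault(gene.id, {})[k] = KCoverage(
                total=total,
                missing={p: tuple(v) for p, v in missing.items()},
            )
    return CoverageReport(k_min=k_min, k_max=k_max, per_parent=per_parent)


# ---------------------------------------------------------------------------
# junctional peptides
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JunctionalPeptideSet:
    """Novel construct peptides absent from every parent protein, per k.

    These arise at element boundaries (plus the control epitope, which has no
    parent); they are reported because they too are expressed — and hence
    tolerized — wherever the construct is expressed.
    """

    per_k: dict[int, frozenset[str]]

    @property
    def counts(self) -> dict[int, int]:
        return {k: len(v) for k, v in self.per_k.items()}

    @property
    def n_total(self) -> int:
        return sum(self.counts.values())

    def rows(self) -> list[dict]:
        return [
            {"k": k, "n_junctional": len(peps),
             "peptides": ",".join(sorted(peps))}
            for k, peps in sorted(self.per_k.items())
        ]

    def to_tsv(self, path: str | Path) -> Path:
        import pandas as pd

        path = Path(path)
        pd.DataFrame(
            self.rows(), columns=["k", "n_junctional", "peptides"]
        ).to_csv(path, sep="\t", index=False)
        return path


def enumerate_junctional_peptides(
    parents: Sequence[ReporterGene],
    construct: TolConstruct,
    k_min: int,
    k_max: int,
) -> JunctionalPeptideSet:
    """Per k: construct k-mer set minus the union of all parent k-mer sets."""
    if k_min > k_max:
        raise ValueError(f"k_min {k_min} > k_max {k_max}")
    per_k: dict[int, frozenset[str]] = {}
    for k in range(k_min, k_max + 1):
        parental: set[str] = set()
        for gene in parents:
            parental |= _kmer_set(gene.protein, k)
        per_k[k] = frozenset(_kmer_set(construct.protein, k) - parental)
    return JunctionalPeptideSet(per_k=per_k)


# ---------------------------------------------------------------------------
# longest parental run (function-disruption proxy)
# ---------------------------------------------------------------------------

class _SuffixAutomaton:
    """Suffix automaton over a reference string; linear-time construction.

    Supports streaming a query string to find the longest substring of the
    query that occurs in the reference — the classic online longest-common-
    substring routine.
    """

    def __init__(self, text: str) -> None:
        self.next: list[dict[str, int]] = [{}]
        self.link: list[int] = [-1]
        self.length: list[int] = [0]
        last = 0
        for ch in text:
            last = self._extend(last, ch)

    def _extend(self, last: int, ch: str) -> int:
        cur = len(self.length)
        self.next.append({})
        self.length.append(self.length[last] + 1)
        self.link.append(-1)
        p = last
        while p != -1 and ch not in self.next[p]:
            self.next[p][ch] = cur
            p = self.link[p]
        if p == -1:
            self.link[cur] = 0
            return cur
        q = self.next[p][ch]
        if self.length[p] + 1 == self.length[q]:
            self.link[cur] = q
            return cur
        clone = len(self.length)
        self.next.append(dict(self.next[q]))
        self.length.append(self.length[p] + 1)
        self.link.append(self.link[q])
        while p != -1 and self.next[p].get(ch) == q:
            self.next[p][ch] = clone
            p = self.link[p]
        self.link[q] = clone
        self.link[cur] = clone
        return cur

    def longest_match(self, query: str) -> int:
        best = cur_len = 0
        state = 0
        for ch in query:
            while state != -1 and ch not in self.next[state]:
                state = self.link[state]
                cur_len = 0 if state == -1 else self.length[state]
            if state == -1:
                state, cur_len = 0, 0
                continue
            state = self.next[state][ch]
            cur_len += 1
            best = max(best, cur_len)
        return best


def longest_parental_run(
    parent: ReporterGene, construct: TolConstruct
) -> int:
    """Length (aa) of the longest parent-protein substring in the construct.

    This is the residual contiguous stretch of one parent that survives
    scrambling — a proxy for how thoroughly the parent's function was
    disrupted. Under the strict adjacency constraint no two same-parent
    elements touch, so the run cannot exceed the parent's largest single
    element.
    """
    automaton = _SuffixAutomaton(construct.protein)
    return automaton.longest_match(parent.protein)


# ---------------------------------------------------------------------------
# peptide export
# ---------------------------------------------------------------------------

def export_peptides(
    construct: TolConstruct,
    k_min: int,
    k_max: int,
    out_path: str | Path,
) -> Path:
    """Write the construct's unique k-mer peptides, one per line.

    Output is uppercase, deduplicated and lexicographically sorted — the
    plain peptide-list dialect accepted by MHC-binding predictors, which
    score the list externally (prediction is outside this tool's scope).
    """
    if k_min > k_max:
        raise ValueError(f"k_min {k_min} > k_max {k_max}")
    peptides: set[str] = set()
    for k in range(k_min, k_max + 1):
        kmers = _kmer_set(construct.protein, k)
        log.info("k=%d: %d unique peptides", k, len(kmers))
        peptides |= kmers
    path = Path(out_path)
    path.write_text(
        "".join(p.upper() + "\n" for p in sorted(peptides))
    )
    return path
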