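"""Evidence integration and candidate calling for the screen's second tier.

A gene enters the candidate list only if it passes the evidence gate — a
chemical-sensitivity phenotype (myriocin, aureobasidin A or caspofungin,
the drugs to which kinase-null cells are hypersensitive) or a curated
genetic/physical interaction with the kinase, its paralog, its regulators
(TORC2, PP2A) or the sphingolipid machinery — and then meets one of three
site-based criteria:

  (a) four or more predicted motif sites;
  (b) exactly three sites, with at least one above the likelihood cutoff
      or known phosphorylated in vivo (PhosphoGRID);
  (c) one or two sites, with likelihood at the cutoff or above AND a known
      in vivo phosphosite among them.

Criterion (b) is encoded as ``n_sites == 3 and (max_likelihood > cutoff or
phosphogrid_site)``; the alternative reading ("3 sites, at least one of
which is above-cutoff or database-identified") collapses to the same
predicate because both the maximum likelihood and the database flag are
per-gene aggregates.  A small number of genes that fail the criteria but
still carry motif sites can be force-included (``manual_include``),
mirroring the asterisked entries of the screen's candidate table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .scan import SiteHit

PHENOTYPE_CODES: Mapping[str, str] = {
    "Myr": "myriocin",
    "AbA": "aureobasidinA",
    "Casp": "caspofungin",
}
VALID_PHENOTYPES = frozenset(PHENOTYPE_CODES.values())


@dataclass(frozen=True)
class EvidenceRecord:
    gene_id: str
    phenotypes: frozenset[str] = frozenset()
    interaction: bool = False
    phosphogrid_positions: frozenset[int] = frozenset()
    go_slim: str = "Biological Process Unknown"
    manual_include: bool = False

    def __post_init__(self) -> None:
        bad = set(self.phenotypes) - VALID_PHENOTYPES
        if bad:
            raise ValueError(f"{self.gene_id}: unknown phenotype labels {sorted(bad)}")
        if any(p <= 0 for p in self.phosphogrid_positions):
            raise ValueError(f"{self.gene_id}: phosphosite positions must be positive")


@dataclass(frozen=True)
class Thresholds:
    """Likelihood cutoffs for criteria (b) and (c).

    The published cutoff is 0.7 on the motif likelihood scale; wording
    differs between the two criteria ("above" vs "a score of"), so the
    comparators are configurable: (b) strict ``>`` and (c) inclusive ``>=``
    by default.
    """

    likelihood_cutoff: float = 0.7
    b_strict: bool = True
    c_strict: bool = False

    def passes_b(self, likelihood: float) -> bool:
        return likelihood > self.likelihood_cutoff if self.b_strict else likelihood >= self.likelihood_cutoff

    def passes_c(self, likelihood: float) -> bool:
        return likelihood > self.likelihood_cutoff if self.c_strict else likelihood >= self.likelihood_cutoff


@dataclass(frozen=True)
class CandidateDecision:
    gene_id: str
    n_sites: int
    max_likelihood: float
    has_phosphogrid_site: bool
    gate_ok: bool
    branch: str  # one of a, b, c, none, manual
    is_candidate: bool


def parse_phenotypes(cell: str) -> frozenset[str]:
    """Map comma-separated codes (Myr/AbA/Casp) to canonical labels."""
    cell = (cell or "").strip()
    if not cell or cell == "N/A":
        return frozenset()
    labels = set()
    for code in cell.split(","):
        code = code.strip()
        if not code:
            continue
        if code not in PHENOTYPE_CODES:
            raise ValueError(f"unknown phenotype code {code!r}")
        labels.add(PHENOTYPE_CODES[code])
    return frozenset(labels)


def load_evidence(path: str | Path) -> list[EvidenceRecord]:
    """Read per-gene evidence from TSV.

    Required column: ``gene_id``.  Optional columns (missing ones default
    to empty/false): ``phenotypes`` (comma-separated Myr/AbA/Casp),
    ``interaction`` (0/1), ``phosphogrid_positions`` (comma-separated
    1-based integers), ``go_slim``, ``manual_include`` (0/1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "gene_id" not in df.columns:
        raise ValueError("evidence table must have a gene_id column")
    if df["gene_id"].duplicated().any():
        dups = df.loc[df["gene_id"].duplicated(), "gene_id"].tolist()
        raise ValueError(f"duplicate gene ids: {dups}")
    records = []
    for _, row in df.iterrows():
        positions = frozenset(
            int(p) for p in row.get("phosphogrid_positions", "").split(",") if p.strip()
        )
        records.append(
            EvidenceRecord(
                gene_id=row["gene_id"],
                phenotypes=parse_phenotypes(row.get("phenotypes", "")),
                interaction=row.get("interaction", "0").strip() == "1",
                phosphogrid_positions=positions,
                go_slim=row.get("go_slim", "").strip() or "Biological Process Unknown",
                manual_include=row.get("manual_include", "0").strip() == "1",
            )
        )
    return records


def write_evidence(records: Iterable[EvidenceRecord], path: str | Path) -> None:
    code_of = {v: k for k, v in PHENOTYPE_CODES.items()}
    rows = [
        {
            "gene_id": r.gene_id,
            "phenotypes": ",".join(sorted(code_of[p] for p in r.phenotypes)),
            "interaction": int(r.interaction),
            "phosphogrid_positions": ",".join(str(p) for p in sorted(r.phosphogrid_positions)),
            "go_slim": r.go_slim,
            "manual_include": int(r.manual_include),
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def classify_candidate(
    hits: Sequence[SiteHit],
    evidence: EvidenceRecord,
    thresholds: Thresholds = Thresholds(),
) -> CandidateDecision:
    """Apply the evidence gate and the (a)/(b)/(c) site criteria to one gene.

    Branches are evaluated a-then-b-then-c so exactly one label is
    assigned; the gate precedes all branches.  ``manual_include`` forces
    candidacy with branch ``manual``.
    """
    for h in hits:
        if h.protein_id != evidence.gene_id:
            raise ValueError(f"hit for {h.protein_id} passed with evidence for {evidence.gene_id}")
    n_sites = len(hits)
    max_likelihood = max((h.score.likelihood for h in hits), default=0.0)
    has_pg = any(h.position in evidence.phosphogrid_positions for h in hits)
    gate_ok = bool(evidence.phenotypes) or evidence.interaction

    branch = "none"
    if n_sites >= 4:
        branch = "a"
    elif n_sites == 3 and (thresholds.passes_b(max_likelihood) or has_pg):
        branch = "b"
    elif n_sites in (1, 2) and thresholds.passes_c(max_likelihood) and has_pg:
        branch = "c"

    is_candidate = gate_ok and branch != "none"
    if evidence.manual_include and not is_candidate:
        branch = "manual"
        is_candidate = True
    return CandidateDecision(
        gene_id=evidence.gene_id,
        n_sites=n_sites,
        max_likelihood=max_likelihood,
        has_phosphogrid_site=has_pg,
        gate_ok=gate_ok,
        branch=branch,
        is_candidate=is_candidate,
    )


def classify_all(
    hits: Sequence[SiteHit],
    evidence: Sequence[EvidenceRecord],
    thresholds: Thresholds = Thresholds(),
) -> list[CandidateDecision]:
    """Group hits by gene and classify every evidence record."""
    by_gene: dict[str, list[SiteHit]] = {}
    for h in hits:
        by_gene.setdefault(h.protein_id, []).append(h)
    return [classify_candidate(by_gene.get(e.gene_id, []), e, thresholds) for e in evidence]


def build_candidate_table(
    decisions: Sequence[CandidateDecision],
    evidence: Sequence[EvidenceRecord],
    hits: Sequence[SiteHit],
) -> pd.DataFrame:
    """Candidate list grouped by GO Slim term, then gene id.

    One row per candidate with its predicted site positions and an
    evidence summary; deterministic ordering (go_slim lexicographic, then
    gene_id).
    """
    ev_by_gene = {e.gene_id: e for e in evidence}
    sites_by_gene: dict[str, list[int]] = {}
    for h in hits:
        sites_by_gene.setdefault(h.protein_id, []).append(h.position)
    code_of = {v: k for k, v in PHENOTYPE_CODES.items()}
    rows = []
    for d in decisions:
        if not d.is_candidate:
            continue
        e = ev_by_gene[d.gene_id]
        summary = sorted(code_of[p] for p in e.phenotypes)
        if e.interaction:
            summary.append("YeastMine")
        rows.append(
            {
                "go_slim": e.go_slim,
                "gene_id": d.gene_id,
                "sites": ",".join(str(p) for p in sorted(sites_by_gene.get(d.gene_id, []))),
                "n_sites": d.n_sites,
                "max_likelihood": d.max_likelihood,
                "evidence": ",".join(summary),
                "branch": d.branch,
            }
        )
    df = pd.DataFrame(
        rows,
        columns=["go_slim", "gene_id", "sites", "n_sites", "max_likelihood", "evidence", "branch"],
    )
    return df.sort_values(["go_slim", "gene_id"], kind="mergesort").reset_index(drop=True)
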