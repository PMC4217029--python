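"""Synthetic-dosage-lethality grading and screen summary statistics.

The screen's second tier overexpresses each candidate from a
galactose-inducible promoter in cells whose kinase activity is titrated
down with an ATP-analog inhibitor (3-MB-PP1 at 0, 1 or 2 uM) acting on an
analog-sensitive kinase allele.  Growth of 10-fold dilution spot series is
compared against a GFP-expressing control construct; dextrose plates (no
overexpression) serve as the toxicity baseline, and a wild-type-kinase
strain distinguishes inhibitor-dependent lethality from plain
overexpression toxicity.

Grades, strongest first (the rubric's descriptions are nested severities,
so the first matching rule wins):

  TOXIC  wild-type strain already grows >=1 spot worse than its control on
         galactose with no inhibitor (unscoreable overexpression toxicity);
  P5     growth phenotype with no inhibitor (+++++);
  P4     strong phenotype (no growth) at 1 uM (++++);
  P3     growth phenotype at 1 uM (+++);
  P2     no phenotype at 1 uM but strong phenotype at 2 uM (++);
  P1     no phenotype at 1 uM but a detectable phenotype at 2 uM (+);
  MINUS  no phenotype at any concentration (-).

A "growth phenotype" is >=1 dilution spot less growth than the control at
the same concentration on galactose, with no such deficit on the dextrose
counterpart; a "strong" phenotype is no growth at all.  Records missing
galactose data grade NA.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

STRAINS = ("analog_sensitive", "wild_type")
CARBONS = ("dextrose", "galactose")
INHIBITOR_UM = (0, 1, 2)

#: condition key: (strain, carbon, inhibitor_uM)
Condition = tuple[str, str, int]


class SDLGrade(enum.Enum):
    MINUS = "MINUS"
    P1 = "P1"
    P2 = "P2"
    P3 = "P3"
    P4 = "P4"
    P5 = "P5"
    TOXIC = "TOXIC"
    NA = "NA"


#: ordered severity scale for the non-toxic grades
GRADE_ORDER: tuple[SDLGrade, ...] = (
    SDLGrade.MINUS,
    SDLGrade.P1,
    SDLGrade.P2,
    SDLGrade.P3,
    SDLGrade.P4,
    SDLGrade.P5,
)
HIT_GRADES = frozenset(GRADE_ORDER[1:])

#: printed score symbols of the candidate table
SYMBOL_TO_GRADE: Mapping[str, SDLGrade] = {
    "+++++": SDLGrade.P5,
    "++++": SDLGrade.P4,
    "+++": SDLGrade.P3,
    "++": SDLGrade.P2,
    "+": SDLGrade.P1,
    "-": SDLGrade.MINUS,
    "TOXIC": SDLGrade.TOXIC,
    "N/A": SDLGrade.NA,
}
GRADE_TO_SYMBOL: Mapping[SDLGrade, str] = {g: s for s, g in SYMBOL_TO_GRADE.items()}


@dataclass
class SDLGrowthRecord:
    """Spot counts for one gene construct and its side-by-side control."""

    gene_id: str
    growth: dict[Condition, int]
    control_growth: dict[Condition, int]
    n_dilutions: int = 5

    def __post_init__(self) -> None:
        for mapping in (self.growth, self.control_growth):
            for cond, spots in mapping.items():
                if not 0 <= spots <= self.n_dilutions:
                    raise ValueError(
                        f"{self.gene_id}: spots {spots} outside [0, {self.n_dilutions}] at {cond}"
                    )


@dataclass(frozen=True)
class SDLGradeResult:
    grade: SDLGrade
    rationale: str


@dataclass(frozen=True)
class GeneCall:
    gene_id: str
    grade: SDLGrade
    rescue: bool
    invitro: str  # plus | plus_minus | minus | NA
    sdl_hit: bool
    substrate_call: bool


@dataclass(frozen=True)
class ScreenSummary:
    n_candidates: int
    n_tested: int
    n_toxic: int
    n_hits: int
    n_hits_with_invitro: int
    n_invitro_positive: int

    @property
    def hit_fraction(self) -> float:
        return self.n_hits / self.n_tested if self.n_tested else 0.0

    @property
    def toxic_fraction(self) -> float:
        return self.n_toxic / self.n_tested if self.n_tested else 0.0

    @property
    def invitro_positive_fraction(self) -> float:
        return (
            self.n_invitro_positive / self.n_hits_with_invitro
            if self.n_hits_with_invitro
            else 0.0
        )


def grade_sdl(record: SDLGrowthRecord) -> SDLGradeResult:
    """Grade one growth record with the dilution-spot rubric (see module
    docstring for the precedence order)."""
    g, c = record.growth, record.control_growth

    required: list[Condition] = [("wild_type", "galactose", 0)]
    for conc in INHIBITOR_UM:
        required.append(("analog_sensitive", "galactose", conc))
        required.append(("analog_sensitive", "dextrose", conc))
    missing = [cond for cond in required if cond not in g or cond not in c]
    if missing:
        return SDLGradeResult(SDLGrade.NA, f"missing condition cells: {missing}")

    def phenotype(conc: int) -> bool:
        gal_deficit = c[("analog_sensitive", "galactose", conc)] - g[("analog_sensitive", "galactose", conc)] >= 1
        dex_deficit = c[("analog_sensitive", "dextrose", conc)] - g[("analog_sensitive", "dextrose", conc)] >= 1
        return gal_deficit and not dex_deficit

    def strong(conc: int) -> bool:
        return g[("analog_sensitive", "galactose", conc)] == 0

    if c[("wild_type", "galactose", 0)] - g[("wild_type", "galactose", 0)] >= 1:
        return SDLGradeResult(SDLGrade.TOXIC, "wild-type strain impaired on galactose without inhibitor")
    if phenotype(0):
        return SDLGradeResult(SDLGrade.P5, "growth phenotype with no inhibitor")
    if strong(1):
        return SDLGradeResult(SDLGrade.P4, "strong growth phenotype at 1 uM")
    if phenotype(1):
        return SDLGradeResult(SDLGrade.P3, "growth phenotype at 1 uM")
    if not phenotype(1) and strong(2):
        return SDLGradeResult(SDLGrade.P2, "no phenotype at 1 uM, strong phenotype at 2 uM")
    if not phenotype(1) and phenotype(2):
        return SDLGradeResult(SDLGrade.P1, "no phenotype at 1 uM, detectable phenotype at 2 uM")
    return SDLGradeResult(SDLGrade.MINUS, "no growth phenotype at any concentration")


INVITRO_POSITIVE = frozenset({"plus", "plus_minus"})
INVITRO_LEVELS = frozenset({"plus", "plus_minus", "minus", "NA"})


def call_hits(
    grades: Mapping[str, SDLGrade],
    rescue: Mapping[str, bool] | None = None,
    invitro: Mapping[str, str] | None = None,
    count_rescued_toxic: bool = True,
) -> dict[str, GeneCall]:
    """Integrate grades with dosage-rescue and in vitro kinase results.

    A gene is an SDL hit if it carries any graded phenotype (P1-P5), or —
    when ``count_rescued_toxic`` — if its overexpression toxicity is
    rescued by co-overexpression of the kinase (the decoy-substrate
    signature).  A substrate call additionally requires detectable
    kinase-specific phosphorylation in vitro ('+' or '+/-').
    """
    rescue = rescue or {}
    invitro = invitro or {}
    calls: dict[str, GeneCall] = {}
    for gene, grade in grades.items():
        iv = invitro.get(gene, "NA")
        if iv not in INVITRO_LEVELS:
            raise ValueError(f"{gene}: invalid in vitro level {iv!r}")
        resc = bool(rescue.get(gene, False))
        sdl_hit = grade in HIT_GRADES or (
            count_rescued_toxic and grade is SDLGrade.TOXIC and resc
        )
        calls[gene] = GeneCall(
            gene_id=gene,
            grade=grade,
            rescue=resc,
            invitro=iv,
            sdl_hit=sdl_hit,
            substrate_call=sdl_hit and iv in INVITRO_POSITIVE,
        )
    return calls


def summarize_screen(calls: Mapping[str, GeneCall]) -> ScreenSummary:
    """Count toxic, hit and in-vitro-positive genes over a set of calls.

    NA-graded genes count as candidates but not as tested; in-vitro counts
    are taken over the SDL hits that were assayed.
    """
    values = list(calls.values())
    tested = [c for c in values if c.grade is not SDLGrade.NA]
    hits = [c for c in tested if c.sdl_hit]
    hits_with_iv = [c for c in hits if c.invitro != "NA"]
    return ScreenSummary(
        n_candidates=len(values),
        n_tested=len(tested),
        n_toxic=sum(c.grade is SDLGrade.TOXIC for c in tested),
        n_hits=len(hits),
        n_hits_with_invitro=len(hits_with_iv),
        n_invitro_positive=sum(c.substrate_call for c in hits_with_iv),
    )


# -- long-format growth table I/O -----------------------------------------


def load_growth_table(path: str | Path) -> list[SDLGrowthRecord]:
    """Read long-format growth TSV with columns gene_id, strain, carbon,
    inhibitor_uM, spots_grown, is_control (plus optional n_dilutions)."""
    df = pd.read_csv(path, sep="\t")
    records = []
    for gene, sub in df.groupby("gene_id", sort=True):
        growth: dict[Condition, int] = {}
        control: dict[Condition, int] = {}
        n_dil = int(sub["n_dilutions"].iloc[0]) if "n_dilutions" in sub.columns else 5
        for _, row in sub.iterrows():
            cond = (row["strain"], row["carbon"], int(row["inhibitor_uM"]))
            target = control if int(row["is_control"]) else growth
            target[cond] = int(row["spots_grown"])
        records.append(SDLGrowthRecord(str(gene), growth, control, n_dilutions=n_dil))
    return records


def write_growth_table(records: Iterable[SDLGrowthRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for is_control, mapping in ((0, rec.growth), (1, rec.control_growth)):
            for (strain, carbon, conc), spots in sorted(mapping.items()):
                rows.append(
                    {
                        "gene_id": rec.gene_id,
                        "strain": strain,
                        "carbon": carbon,
                        "inhibitor_uM": conc,
                        "spots_grown": spots,
                        "is_control": is_control,
                        "n_dilutions": rec.n_dilutions,
                    }
                )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# -- packaged candidate-table fixture --------------------------------------

_INVITRO_SYMBOL = {"+": "plus", "+/-": "plus_minus", "-": "minus", "N/A": "NA"}


def load_table1_fixture(path: str | Path | None = None) -> pd.DataFrame:
    """Load the packaged transcription of the screen's candidate table.

    One row per construct with the printed site positions, evidence,
    SDL score symbol, dosage-rescue and in vitro kinase results.  Rows with
    ``known_substrate == 1`` are the positive-control section (known
    substrates), not screen candidates.
    """
    if path is None:
        from importlib.resources import files

        path = str(files("ypkscreen.data").joinpath("table1_fixture.tsv"))
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def summarize_table1(
    df: pd.DataFrame,
    include_manual: bool = True,
    count_rescued_toxic: bool = True,
) -> ScreenSummary:
    """Screen summary over the candidate rows of the packaged table.

    Known-substrate control rows are excluded; asterisked (manually
    included) candidates are kept unless ``include_manual`` is False.
    """
    sub = df[df["known_substrate"] != "1"]
    if not include_manual:
        sub = sub[sub["manual_include"] != "1"]
    grades = {r["gene_id"]: SYMBOL_TO_GRADE[r["sdl_score"]] for _, r in sub.iterrows()}
    rescue = {r["gene_id"]: r["rescue"] == "+" for _, r in sub.iterrows()}
    invitro = {r["gene_id"]: _INVITRO_SYMBOL[r["invitro"]] for _, r in sub.iterrows()}
    calls = call_hits(grades, rescue, invitro, count_rescued_toxic=count_rescued_toxic)
    return summarize_screen(calls)
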