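"""Cohort summaries and exact association statistics.

Protein status is derived from the two assays: quantitative immunoblot
expression (normalized to the MAX-wild-type GIST430 control line,
inactivation threshold < 0.4) and MAX immunohistochemistry.  A case is
called protein-loss when any performed assay shows loss: IHC can
detect clonal loss in the neoplastic compartment that a whole-lysate
immunoblot misses when non-neoplastic cells contribute residual
signal.  Untested cases are excluded from denominators per comparison,
never imputed.

Association tests are two-tailed Fisher's exact tests computed with
exact integer combinatorics (point-probability definition: the p-value
sums the probabilities of every same-margin table no more probable
than the observed one).  The classical doubling rule is available
behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, floor

import pandas as pd

DEFAULT_PROTEIN_THRESHOLD = 0.4


def protein_loss_call(
    normalized_expression: float, threshold: float = DEFAULT_PROTEIN_THRESHOLD
) -> str:
    """Immunoblot call: ``loss`` iff expression < threshold (strict)."""
    if normalized_expression < 0:
        raise ValueError("normalized expression must be non-negative")
    return "loss" if normalized_expression < threshold else "retained"


def derive_protein_status(
    cohort: pd.DataFrame, threshold: float = DEFAULT_PROTEIN_THRESHOLD
) -> pd.Series:
    """Per-case protein status from the assay columns.

    ``loss`` if any performed assay (immunoblot thresholded at
    ``threshold``, or IHC) shows loss; ``retained`` if at least one
    assay was performed and none shows loss; ``untested`` otherwise.
    """
    expr = cohort["immunoblot_expression"]
    ihc = cohort.get("ihc_status", pd.Series("untested", index=cohort.index))
    out = []
    for e, h in zip(expr, ihc):
        blot = None if pd.isna(e) else protein_loss_call(float(e), threshold)
        calls = [c for c in (blot, None if h == "untested" else h) if c is not None]
        if not calls:
            out.append("untested")
        elif "loss" in calls:
            out.append("loss")
        else:
            out.append("retained")
    return pd.Series(out, index=cohort.index, name="protein_status")


def round_half_up_percent(count: int, denominator: int) -> int:
    """Integer percentage, round half up (printed-table convention)."""
    if denominator == 0:
        raise ZeroDivisionError("empty denominator")
    return int(floor(100.0 * count / denominator + 0.5))


@dataclass
class FrequencyRow:
    stratum: str
    count: int
    denominator: int
    percent: int | None  # None when the stratum denominator is 0

    @property
    def fraction(self) -> float:
        return self.count / self.denominator if self.denominator else float("nan")


def summarize(
    cohort: pd.DataFrame,
    column: str,
    positive: str,
    by: str | None = None,
    exclude: tuple[str, ...] = ("untested", "unknown"),
) -> list[FrequencyRow]:
    """Frequency of ``positive`` values of ``column``, optionally per
    stratum of ``by``.  Values in ``exclude`` (and missing values)
    leave the denominator.
    """
    if cohort.empty:
        raise ValueError("cohort table is empty")
    tested = cohort[~cohort[column].isin(exclude) & cohort[column].notna()]
    groups = [("all", tested)] if by is None else list(tested.groupby(by, sort=False))
    rows = []
    for name, sub in groups:
        denom = len(sub)
        count = int((sub[column] == positive).sum())
        rows.append(
            FrequencyRow(
                str(name),
                count,
                denom,
                round_half_up_percent(count, denom) if denom else None,
            )
        )
    return rows


@dataclass(frozen=True)
class ContingencyTable2x2:
    a: int
    b: int
    c: int
    d: int
    row_labels: tuple[str, str] = ("row1", "row2")
    col_labels: tuple[str, str] = ("col1", "col2")

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("cells must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table must have at least one positive margin")

    @property
    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)

    @property
    def degenerate(self) -> bool:
        return (
            self.a + self.b == 0
            or self.c + self.d == 0
            or self.a + self.c == 0
            or self.b + self.d == 0
        )


def fisher_exact_2x2(
    table: ContingencyTable2x2 | tuple[int, int, int, int],
    method: str = "point_probability",
) -> float:
    """Two-tailed Fisher exact p-value.

    Computed with exact integer combinatorics on the hypergeometric
    support, so ties between equally probable tables are resolved
    exactly rather than to floating-point tolerance.  ``method`` is
    ``point_probability`` (default; sum of all same-margin tables at
    most as probable as the observed one) or ``doubling`` (twice the
    smaller tail, capped at 1).  A table with a zero margin carries no
    information and returns p = 1.
    """
    if not isinstance(table, ContingencyTable2x2):
        table = ContingencyTable2x2(*table)
    a, b, c, d = table.cells
    if table.degenerate:
        return 1.0
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    weights = {k: comb(r1, k) * comb(r2, c1 - k) for k in range(lo, hi + 1)}
    total = comb(n, c1)
    w_obs = weights[a]
    if method == "point_probability":
        num = sum(w for w in weights.values() if w <= w_obs)
    elif method == "doubling":
        lower = sum(w for k, w in weights.items() if k <= a)
        upper = sum(w for k, w in weights.items() if k >= a)
        num = min(2 * min(lower, upper), total)
    else:
        raise ValueError(f"unknown method {method!r}")
    return num / total


@dataclass
class AssociationResult:
    table: ContingencyTable2x2
    p_value: float
    n_used: int
    n_excluded: int


def associate(
    cohort: pd.DataFrame,
    factor_a: tuple[str, str],
    factor_b: tuple[str, str],
    exclude: tuple[str, ...] = ("untested", "unknown"),
    method: str = "point_probability",
) -> AssociationResult:
    """Fisher association between two binary factors of the cohort.

    Each factor is ``(column, positive_level)``; rows whose value in
    either column is missing or in ``exclude`` are removed first (the
    number removed is recorded).  A factor that is constant after
    filtering is an error naming the factor.
    """
    col_a, pos_a = factor_a
    col_b, pos_b = factor_b
    keep = cohort.copy()
    for col in (col_a, col_b):
        keep = keep[~keep[col].isin(exclude) & keep[col].notna()]
    n_excluded = len(cohort) - len(keep)
    for col in (col_a, col_b):
        if keep[col].nunique() < 2:
            raise ValueError(
                f"factor {col!r} has a single observed level after filtering; "
                "association is undefined"
            )
    ia = keep[col_a] == pos_a
    ib = keep[col_b] == pos_b
    table = ContingencyTable2x2(
        int((ia & ib).sum()),
        int((ia & ~ib).sum()),
        int((~ia & ib).sum()),
        int((~ia & ~ib).sum()),
        row_labels=(f"{col_a}={pos_a}", f"{col_a}!={pos_a}"),
        col_labels=(f"{col_b}={pos_b}", f"{col_b}!={pos_b}"),
    )
    return AssociationResult(table, fisher_exact_2x2(table, method=method), len(keep), n_excluded)


def cohort_report(cohort: pd.DataFrame, threshold: float = DEFAULT_PROTEIN_THRESHOLD) -> dict:
    """The standard frequency summary of a 76-style cohort table.

    Returns genomic-mutation and protein-loss frequencies overall and
    per aetiology group, plus the raw immunoblot and IHC assay
    frequencies.
    """
    df = cohort.copy()
    df["protein_status"] = derive_protein_status(df, threshold)
    df["immunoblot_status"] = [
        "untested" if pd.isna(e) else protein_loss_call(float(e), threshold)
        for e in df["immunoblot_expression"]
    ]
    out: dict[str, FrequencyRow] = {}
    out["genomic_overall"] = summarize(df, "genomic_max", "mutant")[0]
    for row in summarize(df, "genomic_max", "mutant", by="group"):
        out[f"genomic_{row.stratum}"] = row
    out["protein_overall"] = summarize(df, "protein_status", "loss")[0]
    for row in summarize(df, "protein_status", "loss", by="group"):
        out[f"protein_{row.stratum}"] = row
    out["immunoblot"] = summarize(df, "immunoblot_status", "loss")[0]
    out["ihc"] = summarize(df, "ihc_status", "loss")[0]
    return out
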