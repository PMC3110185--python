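"""Chemical x assay data matrix and univariate association screening.

The substrate for the predictive-modelling stages is a complete matrix of
chemicals (rows) by assay/endpoint columns holding AC50 values in molar
units with a default of 1 M for inactive combinations (in-vivo LEL columns
use an explicit infinite sentinel instead). Two derived views drive the
statistics:

* a dichotomized 0/1 activity matrix (active iff the value beats the
  inactive default), feeding Fisher's exact test on 2x2 input/output
  contingency tables;
* potency scores ``-log10(AC50 [M])`` — zero for inactive pairs, larger for
  more potent — feeding Welch's t-test of input scores between
  output-positive and output-negative chemicals.

Pathway perturbation scores (PS) collapse a set of assay columns mapped to
one pathway into their per-chemical minimum AC50 and append as new columns.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .doseresponse import ENDPOINTS, INACTIVE_AC50_M

KIND_AC50 = "in_vitro_ac50"
KIND_LEL = "in_vivo_lel"
KIND_PS = "pathway_ps"

LEL_INACTIVE = math.inf  # sentinel for in-vivo endpoints with no effective dose


class SchemaError(ValueError):
    pass


class DomainError(ValueError):
    pass


def _infer_kind(column: str) -> str:
    if column.startswith("lel_"):
        return KIND_LEL
    if column.startswith("ps_"):
        return KIND_PS
    return KIND_AC50


@dataclass
class AssayMatrix:
    """Complete chemicals x columns value matrix (no missing cells).

    ``values`` is indexed by chemical id; ``kinds`` maps each column to
    in_vitro_ac50 / in_vivo_lel / pathway_ps (inferred from the ``lel_`` and
    ``ps_`` column-id prefixes when not given).
    """

    values: pd.DataFrame
    kinds: dict = field(default_factory=dict)

    def __post_init__(self):
        cols = list(self.values.columns)
        if len(set(cols)) != len(cols):
            raise SchemaError("duplicate column ids")
        if self.values.isna().any().any():
            raise SchemaError("matrix has missing cells; inactivity is a value, not absence")
        self.kinds = {c: self.kinds.get(c, _infer_kind(c)) for c in cols}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_calls(cls, calls: pd.DataFrame, extra: pd.DataFrame | None = None,
                   chemicals=None) -> "AssayMatrix":
        """Build the matrix from an activity-call table.

        Emits one molar-AC50 column per ES endpoint (inactive = 1 M);
        ``extra`` columns (e.g. external assay AC50s or ``lel_`` endpoints)
        are joined on chemical id and must not collide.
        """
        if "ac50_M" not in calls.columns:
            raise SchemaError("call table lacks ac50_M")
        wide = calls.pivot_table(index="chemical", columns="endpoint",
                                 values="ac50_M", aggfunc="min")
        wide = wide.reindex(columns=list(ENDPOINTS)).fillna(INACTIVE_AC50_M)
        wide.columns.name = None
        if chemicals is not None:
            wide = wide.reindex(index=list(chemicals), fill_value=INACTIVE_AC50_M)
        if extra is not None:
            overlap = set(wide.columns) & set(extra.columns)
            if overlap:
                raise SchemaError(f"duplicate column ids: {sorted(overlap)}")
            wide = wide.join(extra, how="left")
            if wide.isna().any().any():
                raise SchemaError("extra columns do not cover all chemicals")
        return cls(wide.sort_index())

    # -- derived views ----------------------------------------------------

    def inactive_sentinel(self, column: str) -> float:
        return LEL_INACTIVE if self.kinds[column] == KIND_LEL else INACTIVE_AC50_M

    def dichotomize(self) -> pd.DataFrame:
        """0/1 activity matrix: 1 iff the value beats the inactive default."""
        out = {}
        for c in self.values.columns:
            out[c] = (self.values[c] < self.inactive_sentinel(c)).astype(int)
        return pd.DataFrame(out, index=self.values.index)

    def scale_scores(self) -> pd.DataFrame:
        """Potency scores -log10(AC50 [M]) for AC50/PS columns.

        1 M (inactive) maps to exactly 0; more potent chemicals score
        higher. LEL columns carry no molar potency and are excluded.
        """
        cols = [c for c in self.values.columns if self.kinds[c] != KIND_LEL]
        sub = self.values[cols]
        if (sub <= 0).any().any():
            raise DomainError("AC50 values must be positive")
        return -np.log10(sub)

    # -- IO ----------------------------------------------------------------

    def to_csv(self, path) -> None:
        self.values.to_csv(path, index_label="chemical")

    @classmethod
    def read_csv(cls, path, kinds: dict | None = None) -> "AssayMatrix":
        values = pd.read_csv(path, index_col="chemical")
        return cls(values, dict(kinds or {}))


# ---------------------------------------------------------------------------
# Univariate tests


@dataclass(frozen=True)
class ContingencyTable:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass(frozen=True)
class AssociationResult:
    input_col: str
    output_col: str
    method: str  # "fisher" | "ttest"
    statistic: float
    p_value: float
    table: ContingencyTable | tuple  # 2x2 for fisher, (n_pos, n_neg) for ttest
    direction: int  # +1 higher input activity among output-positives
    degenerate: bool = False
    testable: bool = True


def contingency(x, y) -> ContingencyTable:
    x = np.asarray(x).astype(bool)
    y = np.asarray(y).astype(bool)
    if x.shape != y.shape:
        raise SchemaError("input/output vectors differ in length")
    return ContingencyTable(
        int(np.sum(x & y)), int(np.sum(x & ~y)),
        int(np.sum(~x & y)), int(np.sum(~x & ~y)),
    )


def fisher_association(x, y, input_col: str = "input",
                       output_col: str = "output") -> AssociationResult:
    """Two-sided Fisher's exact test of two dichotomized columns.

    The p-value sums hypergeometric probabilities of tables no more likely
    than the observed one (conditional on both margins). Columns with a
    degenerate margin (all 0 or all 1) return p = 1 flagged degenerate.
    """
    t = contingency(x, y)
    direction = int(np.sign(t.TP * t.TN - t.FP * t.FN))
    if t.TP + t.FP in (0, t.total) or t.TP + t.FN in (0, t.total):
        return AssociationResult(input_col, output_col, "fisher", np.nan, 1.0,
                                 t, 0, degenerate=True, testable=False)
    odds, p = stats.fisher_exact([[t.TP, t.FP], [t.FN, t.TN]], alternative="two-sided")
    return AssociationResult(input_col, output_col, "fisher", float(odds),
                             float(min(p, 1.0)), t, direction)


def ttest_association(scores, y, input_col: str = "input",
                      output_col: str = "output") -> AssociationResult:
    """Welch's t-test of input potency scores between output groups.

    Positive direction means output-positive chemicals carry higher scores.
    Groups smaller than 2 are not testable; two zero-variance groups with
    different means are flagged degenerate (the infinite t is guarded).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(bool)
    pos, neg = scores[y], scores[~y]
    sizes = (len(pos), len(neg))
    if min(sizes) < 2:
        return AssociationResult(input_col, output_col, "ttest", np.nan, 1.0,
                                 sizes, 0, degenerate=False, testable=False)
    direction = int(np.sign(pos.mean() - neg.mean()))
    if pos.var(ddof=1) == 0 and neg.var(ddof=1) == 0:
        if pos.mean() == neg.mean():
            return AssociationResult(input_col, output_col, "ttest", 0.0, 1.0,
                                     sizes, 0, degenerate=True)
        return AssociationResult(input_col, output_col, "ttest",
                                 math.inf * direction, 0.0, sizes, direction,
                                 degenerate=True)
    t, p = stats.ttest_ind(pos, neg, equal_var=False)
    return AssociationResult(input_col, output_col, "ttest", float(t),
                             float(p), sizes, direction)


# ---------------------------------------------------------------------------
# Pathway perturbation scores


def load_pathway_map(source) -> dict:
    """Load {pathway id: [column ids]} from a JSON path or mapping."""
    if isinstance(source, dict):
        pmap = source
    else:
        with open(source) as fh:
            pmap = json.load(fh)
    for pathway, cols in pmap.items():
        if not cols:
            raise SchemaError(f"pathway {pathway!r} maps to no columns")
    return {p: list(cols) for p, cols in pmap.items()}


def pathway_score(matrix: AssayMatrix, pathway_map: dict) -> pd.DataFrame:
    """PS columns: per-chemical minimum AC50 over each pathway's assays.

    All-inactive rows keep the 1 M default. Returns the new ``ps_`` columns
    (molar) indexed like the matrix.
    """
    pathway_map = load_pathway_map(pathway_map)
    out = {}
    for pathway, cols in pathway_map.items():
        missing = [c for c in cols if c not in matrix.values.columns]
        if missing:
            raise SchemaError(f"pathway {pathway!r} maps to unknown columns {missing}")
        bad = [c for c in cols if matrix.kinds[c] == KIND_LEL]
        if bad:
            raise SchemaError(f"pathway {pathway!r} maps to non-AC50 columns {bad}")
        out[f"ps_{pathway}"] = matrix.values[cols].min(axis=1)
    return pd.DataFrame(out, index=matrix.values.index)


def with_pathway_scores(matrix: AssayMatrix, pathway_map: dict) -> AssayMatrix:
    ps = pathway_score(matrix, pathway_map)
    overlap = set(ps.columns) & set(matrix.values.columns)
    if overlap:
        raise SchemaError(f"duplicate column ids: {sorted(overlap)}")
    return AssayMatrix(matrix.values.join(ps), dict(matrix.kinds))


# ---------------------------------------------------------------------------
# Association screen


RESULT_COLUMNS = ["input", "output", "method", "statistic", "p", "TP", "FP",
                  "FN", "TN", "direction", "degenerate", "significant"]


def association_screen(matrix: AssayMatrix, inputs=None, outputs=None,
                       alpha: float = 0.1, methods=("fisher", "ttest"),
                       bh_adjust: bool = False) -> pd.DataFrame:
    """Run both univariate tests for every input x output column pair.

    Returns a table sorted by ascending p (lexicographic input/output/method
    tie-break) with a ``significant`` flag at p <= alpha (raw p by default;
    Benjamini-Hochberg adjusted when ``bh_adjust``). Input == output pairs
    are skipped; the t-test applies only to AC50/PS (score-bearing) inputs.
    """
    cols = list(matrix.values.columns)
    inputs = cols if inputs is None else list(inputs)
    outputs = cols if outputs is None else list(outputs)
    for c in inputs + outputs:
        if c not in matrix.values.columns:
            raise SchemaError(f"unknown column {c!r}")
    binary = matrix.dichotomize()
    scores = matrix.scale_scores()

    rows = []
    for inp in inputs:
        for out in outputs:
            if inp == out:
                continue
            results = []
            if "fisher" in methods:
                results.append(fisher_association(binary[inp], binary[out], inp, out))
            if "ttest" in methods and inp in scores.columns:
                results.append(ttest_association(scores[inp], binary[out], inp, out))
            for r in results:
                t = r.table if isinstance(r.table, ContingencyTable) else None
                rows.append((
                    r.input_col, r.output_col, r.method, r.statistic, r.p_value,
                    *( (t.TP, t.FP, t.FN, t.TN) if t else (np.nan,) * 4 ),
                    r.direction, r.degenerate, False,
                ))
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if table.empty:
        return table
    if bh_adjust:
        table["p_adj"] = _bh(table["p"].to_numpy())
        table["significant"] = table["p_adj"] <= alpha
    else:
        table["significant"] = table["p"] <= alpha
    return table.sort_values(["p", "input", "output", "method"], ignore_index=True)


def _bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return np.clip(adj, 0.0, 1.0)
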