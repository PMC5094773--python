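"""Three-step cervical-length triage model.

At each second-trimester screening visit a woman is classified
HIGH_RISK (refer for cerclage / intensified care), DISCHARGE (leave
surveillance: low risk of preterm birth) or CONTINUE (next visit):

* step A uses CL at 13+0-15+6 weeks alone (two thresholds);
* step B uses CL at 16+0-18+6 weeks and the percentage shortening since A;
* step C (terminal) combines CL at A, B and 20+0-22+6 weeks with interval
  shortening; anyone not flagged high risk there leaves surveillance.

The default thresholds are the published rule set; ``derive_triage_model``
re-derives a model of the same shape from labelled data under a cap on the
false-low-risk rate (high-risk women among discharge calls), step 1 and 2 by
constrained grid search and step 3 by a deterministic Gini decision tree
whose leaves are labelled to respect the cumulative cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .cohort import PregnancyRecord, Timepoint, cohort_to_frame, pct_delta_cl


class Decision(str, Enum):
    HIGH_RISK = "HIGH_RISK"
    DISCHARGE = "DISCHARGE"
    CONTINUE = "CONTINUE"


class FinalStatus(str, Enum):
    HIGH_RISK = "HIGH_RISK"
    DISCHARGE = "DISCHARGE"
    COMPLETED = "COMPLETED"  # reached terminal visit C without a high-risk call


#: Final statuses that mean the woman was called low risk.
LOW_RISK_FINALS = (FinalStatus.DISCHARGE, FinalStatus.COMPLETED)


@dataclass(frozen=True)
class TriageModelSpec:
    """Threshold set defining the 3-step model (defaults: published rules).

    Step A: high if CL < ``a_high_lt``; discharge if CL >= ``a_low_ge``.
    Step B: high if CL < ``b_high_cl_lt`` OR %ΔCL(A-B) >= ``b_high_delta_ge``;
    else discharge if CL >= ``b_low_cl_ge`` OR %ΔCL(A-B) < ``b_low_delta_lt``
    (``b_low_rule="and"`` switches the discharge rule to a conjunction).
    Step C: high if (CL_A < ``c_rule1_a_lt`` AND %ΔCL over
    ``c_rule1_delta_interval`` >= ``c_rule1_delta_ge``) OR CL_C <=
    ``c_rule2_c_le`` OR (CL_A >= ``c_rule3_a_ge`` AND CL_B < ``c_rule3_b_lt``);
    otherwise surveillance is complete.
    """

    a_high_lt: float = 19.0
    a_low_ge: float = 42.0
    b_high_cl_lt: float = 23.0
    b_high_delta_ge: float = 21.0
    b_low_cl_ge: float = 38.0
    b_low_delta_lt: float = 6.0
    c_rule1_a_lt: float = 28.0
    c_rule1_delta_ge: float = 5.0
    c_rule2_c_le: float = 24.0
    c_rule3_a_ge: float = 24.0
    c_rule3_b_lt: float = 26.0
    c_rule1_delta_interval: str = "A-C"  # or "B-C"
    b_low_rule: str = "or"  # or "and"

    def __post_init__(self) -> None:
        if not self.a_high_lt < self.a_low_ge:
            raise ValueError("a_high_lt must be < a_low_ge")
        if not self.b_high_cl_lt < self.b_low_cl_ge:
            raise ValueError("b_high_cl_lt must be < b_low_cl_ge")
        for nm in ("a_high_lt", "a_low_ge", "b_high_cl_lt", "b_low_cl_ge",
                   "c_rule1_a_lt", "c_rule2_c_le", "c_rule3_a_ge", "c_rule3_b_lt"):
            v = getattr(self, nm)
            if not 5.0 <= v <= 60.0:
                raise ValueError(f"{nm}={v} outside [5, 60] mm")
        for nm in ("b_high_delta_ge", "b_low_delta_lt", "c_rule1_delta_ge"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{nm}={v} outside [0, 100] %")
        if self.c_rule1_delta_interval not in ("A-C", "B-C"):
            raise ValueError("c_rule1_delta_interval must be 'A-C' or 'B-C'")
        if self.b_low_rule not in ("or", "and"):
            raise ValueError("b_low_rule must be 'or' or 'and'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TriageModelSpec":
        return cls(**d)


@dataclass
class TriageOutcome:
    decisions: dict[Timepoint, Decision]
    exit_timepoint: Timepoint
    final: FinalStatus
    scans_used: int
    missed_visits: tuple[Timepoint, ...] = ()

    def __post_init__(self) -> None:
        order = list(Timepoint)
        if self.scans_used != order.index(self.exit_timepoint) + 1:
            raise ValueError("scans_used must equal the index of exit_timepoint")


def classify_A(cl_a: Optional[float], model: TriageModelSpec) -> Decision:
    """First-visit rule; a missing measurement continues surveillance."""
    if cl_a is None:
        return Decision.CONTINUE
    if cl_a < model.a_high_lt:
        return Decision.HIGH_RISK
    if cl_a >= model.a_low_ge:
        return Decision.DISCHARGE
    return Decision.CONTINUE


def classify_B(cl_a: Optional[float], cl_b: Optional[float],
               model: TriageModelSpec) -> Decision:
    """Second-visit rule; the high rule is evaluated before the low rule.

    With cl_a absent the ΔCL clauses are inert (treated false); with cl_b
    absent no classification is possible and the woman continues.
    """
    if cl_b is None:
        return Decision.CONTINUE
    delta = pct_delta_cl(cl_a, cl_b) if cl_a is not None else None
    if cl_b < model.b_high_cl_lt or (delta is not None and delta >= model.b_high_delta_ge):
        return Decision.HIGH_RISK
    cl_low = cl_b >= model.b_low_cl_ge
    delta_low = delta is not None and delta < model.b_low_delta_lt
    low = (cl_low or delta_low) if model.b_low_rule == "or" else (cl_low and delta_low)
    if low:
        return Decision.DISCHARGE
    return Decision.CONTINUE


def classify_C(cl_a: Optional[float], cl_b: Optional[float], cl_c: Optional[float],
               model: TriageModelSpec) -> Decision:
    """Terminal rule: HIGH_RISK if any of three clauses fires, else DISCHARGE.

    Clauses whose inputs are unobserved are inert.
    """
    if model.c_rule1_delta_interval == "A-C":
        early = cl_a
    else:
        early = cl_b
    delta = pct_delta_cl(early, cl_c) if (early is not None and cl_c is not None) else None
    rule1 = (cl_a is not None and cl_a < model.c_rule1_a_lt
             and delta is not None and delta >= model.c_rule1_delta_ge)
    rule2 = cl_c is not None and cl_c <= model.c_rule2_c_le
    rule3 = (cl_a is not None and cl_a >= model.c_rule3_a_ge
             and cl_b is not None and cl_b < model.c_rule3_b_lt)
    if rule1 or rule2 or rule3:
        return Decision.HIGH_RISK
    return Decision.DISCHARGE


def run_triage(record: Union[PregnancyRecord, dict], model) -> TriageOutcome:
    """Apply the sequential model to one record; pure and deterministic.

    ``model`` is a TriageModelSpec or a DerivedTriageModel (which replaces
    the step-C rule with its fitted tree).  Raises ValueError for a record
    with no CL at any timepoint (ineligible).
    """
    if isinstance(record, PregnancyRecord):
        cl_a, cl_b, cl_c = record.cl_a, record.cl_b, record.cl_c
    else:
        def _get(k):
            v = record.get(k)
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v
        cl_a, cl_b, cl_c = _get("cl_a"), _get("cl_b"), _get("cl_c")
    if cl_a is None and cl_b is None and cl_c is None:
        raise ValueError("record has no CL at any timepoint; ineligible for triage")

    spec: TriageModelSpec = model.spec if isinstance(model, DerivedTriageModel) else model
    missed = tuple(
        tp for tp, v in zip(Timepoint, (cl_a, cl_b, cl_c)) if v is None
    )

    decisions: dict[Timepoint, Decision] = {}
    d = classify_A(cl_a, spec)
    decisions[Timepoint.A] = d
    if d is not Decision.CONTINUE:
        final = FinalStatus.HIGH_RISK if d is Decision.HIGH_RISK else FinalStatus.DISCHARGE
        return TriageOutcome(decisions, Timepoint.A, final, 1, missed)

    d = classify_B(cl_a, cl_b, spec)
    decisions[Timepoint.B] = d
    if d is not Decision.CONTINUE:
        final = FinalStatus.HIGH_RISK if d is Decision.HIGH_RISK else FinalStatus.DISCHARGE
        return TriageOutcome(decisions, Timepoint.B, final, 2, missed)

    if isinstance(model, DerivedTriageModel) and model.step_c_tree is not None:
        d = model.classify_c(cl_a, cl_b, cl_c)
    else:
        d = classify_C(cl_a, cl_b, cl_c, spec)
    decisions[Timepoint.C] = d
    final = FinalStatus.HIGH_RISK if d is Decision.HIGH_RISK else FinalStatus.COMPLETED
    return TriageOutcome(decisions, Timepoint.C, final, 3, missed)


def triage_cohort(records: Sequence[PregnancyRecord], model) -> pd.DataFrame:
    """Per-record outcome table (id, decisions, final status, scans used)."""
    rows = []
    for rec in records:
        out = run_triage(rec, model)
        rows.append(
            {
                "id": rec.id,
                "decision_A": out.decisions.get(Timepoint.A, Decision.CONTINUE).value
                if Timepoint.A in out.decisions else "",
                "decision_B": out.decisions[Timepoint.B].value
                if Timepoint.B in out.decisions else "",
                "decision_C": out.decisions[Timepoint.C].value
                if Timepoint.C in out.decisions else "",
                "final": out.final.value,
                "scans_used": out.scans_used,
            }
        )
    return pd.DataFrame(
        rows, columns=["id", "decision_A", "decision_B", "decision_C", "final", "scans_used"]
    )


# ===========================================================================
# Derivation: constrained grid search (steps 1-2) + deterministic CART (step 3)
# ===========================================================================


@dataclass(frozen=True)
class DerivationConstraints:
    """Search constraints: objective is the number of women resolved per step
    subject to a cap on the false-low-risk rate.

    ``constraint_scope="discharges"`` caps high-risk women as a fraction of
    cumulative discharge calls (the default reading of "low false positive
    rate"); ``"group2"`` instead caps discharged high-risk women as a
    fraction of all high-risk women.
    """

    max_false_low_risk_rate: float = 0.05
    cl_grid: tuple[int, int] = (10, 50)  # inclusive integer mm range
    pct_grid: tuple[int, int] = (0, 40)  # inclusive integer % range
    tree_max_depth: int = 3
    tree_min_leaf: int = 10
    constraint_scope: str = "discharges"

    def __post_init__(self) -> None:
        if not 0.0 < self.max_false_low_risk_rate < 1.0:
            raise ValueError("max_false_low_risk_rate must be in (0, 1)")
        if self.constraint_scope not in ("discharges", "group2"):
            raise ValueError("constraint_scope must be 'discharges' or 'group2'")

    def cl_values(self) -> np.ndarray:
        return np.arange(self.cl_grid[0], self.cl_grid[1] + 1)

    def pct_values(self) -> np.ndarray:
        return np.arange(self.pct_grid[0], self.pct_grid[1] + 1)


def _feasible(disc_g2: float, disc_n: float, total_g2: int,
              constraints: DerivationConstraints) -> bool:
    r = constraints.max_false_low_risk_rate
    if constraints.constraint_scope == "discharges":
        return disc_g2 <= r * disc_n
    return disc_g2 <= r * total_g2


def _search_step1(cl_a: np.ndarray, y: np.ndarray,
                  constraints: DerivationConstraints, total_g2: int):
    """Exhaustive search over (a_high_lt, a_low_ge) pairs, a_high < a_low.

    Maximises resolved (HIGH + DISCHARGE) count subject to the false-low-risk
    cap on discharges; ties prefer the smallest discharge region (largest
    a_low) then the smallest a_high.
    """
    grid = constraints.cl_values()
    obs = ~np.isnan(cl_a)
    v, lab = cl_a[obs], y[obs]
    high_n = np.array([(v < t).sum() for t in grid])
    disc_n = np.array([(v >= t).sum() for t in grid])
    disc_g2 = np.array([lab[v >= t].sum() for t in grid])

    best = None  # (resolved, a_low, -a_high) lexicographic max
    for i, t_high in enumerate(grid):
        for j, t_low in enumerate(grid):
            if t_high >= t_low:
                continue
            if not _feasible(disc_g2[j], disc_n[j], total_g2, constraints):
                continue
            key = (high_n[i] + disc_n[j], t_low, -t_high)
            if best is None or key > best[0]:
                best = (key, float(t_high), float(t_low),
                        int(disc_n[j]), int(disc_g2[j]))
    if best is None:  # no feasible pair resolves anyone: degenerate model
        return None
    _, a_high, a_low, dn, dg2 = best
    return a_high, a_low, dn, dg2


def _search_step2(cl_b: np.ndarray, d_ab: np.ndarray, y: np.ndarray,
                  constraints: DerivationConstraints, total_g2: int,
                  carried_disc_n: int, carried_disc_g2: int):
    """Search (b_high_cl_lt, b_high_delta_ge, b_low_cl_ge, b_low_delta_lt).

    The discharge count for every (cl, delta) low-rule pair is obtained from
    2-D cumulative histograms, so the inner sweep is O(grid^2) per high rule.
    """
    G = constraints.cl_values().astype(float)
    D = constraints.pct_values().astype(float)
    nG, nD = len(G), len(D)
    n = len(cl_b)
    cl_obs = ~np.isnan(cl_b)
    # Low rule clause indices: cl_b >= G[k] holds for k <= kv; NaN never holds.
    kv = np.where(cl_obs, np.searchsorted(G, np.nan_to_num(cl_b, nan=-1e9),
                                          side="right") - 1, -1)
    # d_ab < D[m] holds for m >= mv; NaN (inert) never holds.
    mv = np.where(np.isnan(d_ab), nD,
                  np.searchsorted(D, np.nan_to_num(d_ab, nan=1e9), side="right"))

    best = None
    y_f = y.astype(float)
    for t_h in G:
        high_cl = cl_obs & (cl_b < t_h)
        for d_h in D:
            high = high_cl | (d_ab >= d_h)  # NaN >= x is False
            rem = ~high
            m = int(rem.sum())
            n_high = n - m
            if m == 0:
                key = (n_high, G[-1], -D[0], -t_h, -d_h)
                cand = (key, t_h, d_h, float(G[-1]), float(D[0]), 0, 0)
                if best is None or key > best[0]:
                    best = cand
                continue
            kv_r, mv_r, y_r = kv[rem], mv[rem], y_f[rem]
            # H[k+1, m] histograms over (kv, mv); prefix in k, suffix in m
            H = np.zeros((nG + 1, nD + 1))
            H2 = np.zeros((nG + 1, nD + 1))
            np.add.at(H, (kv_r + 1, np.minimum(mv_r, nD)), 1.0)
            np.add.at(H2, (kv_r + 1, np.minimum(mv_r, nD)), y_r)
            # not_disc(k, m) = #(kv < k  AND  mv > m)
            ck = np.cumsum(H, axis=0)  # ck[k] = #(kv+1 <= k) = #(kv < k)
            ck2 = np.cumsum(H2, axis=0)
            sm = np.cumsum(ck[:, ::-1], axis=1)[:, ::-1]  # suffix over m
            sm2 = np.cumsum(ck2[:, ::-1], axis=1)[:, ::-1]
            # For threshold indices (k over G, m over D):
            # disc = m_rem - #(kv < k and mv >= m+1) = m_rem - sm[k, m+1]
            not_disc = sm[:nG, 1:]
            not_disc_g2 = sm2[:nG, 1:]
            disc_n = m - not_disc
            disc_g2 = y_r.sum() - not_disc_g2
            tot_n = carried_disc_n + disc_n
            tot_g2 = carried_disc_g2 + disc_g2
            if constraints.constraint_scope == "discharges":
                feas = tot_g2 <= constraints.max_false_low_risk_rate * tot_n
            else:
                feas = tot_g2 <= constraints.max_false_low_risk_rate * total_g2
            resolved = n_high + disc_n
            # model invariant: the low CL threshold must exceed the high one
            resolved = np.where(feas & (G[:, None] > t_h), resolved, -1)
            flat = int(np.argmax(resolved))  # first max: lowest k, then lowest m
            k_best, m_best = divmod(flat, nD)
            r_best = resolved[k_best, m_best]
            if r_best < 0:
                continue
            # conservative tie-break inside this high rule: among equal
            # resolved, prefer largest t_low then smallest d_low
            ties = np.argwhere(resolved == r_best)
            k_best, m_best = max(ties, key=lambda km: (km[0], -km[1]))
            key = (int(r_best), G[k_best], -D[m_best], -t_h, -d_h)
            cand = (key, float(t_h), float(d_h), float(G[k_best]), float(D[m_best]),
                    int(disc_n[k_best, m_best]), int(disc_g2[k_best, m_best]))
            if best is None or key > best[0]:
                best = cand
    if best is None:
        return None
    _, t_h, d_h, t_l, d_l, dn, dg2 = best
    return t_h, d_h, t_l, d_l, dn, dg2


# --- deterministic CART ----------------------------------------------------

STEP3_FEATURES = ("cl_a", "cl_b", "cl_c", "d_ab", "d_bc", "d_ac")


@dataclass
class _TreeNode:
    n: int
    n_pos: int
    feature: Optional[int] = None
    threshold: Optional[float] = None
    missing_left: bool = True
    left: Optional["_TreeNode"] = None
    right: Optional["_TreeNode"] = None
    leaf_id: int = -1
    label: Decision = Decision.DISCHARGE

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


def _gini(n_pos: float, n: float) -> float:
    if n == 0:
        return 0.0
    p = n_pos / n
    return 2.0 * p * (1.0 - p)


class DecisionTree:
    """Binary Gini CART on a fixed feature set, fully deterministic.

    Split candidates are midpoints between consecutive distinct observed
    values; rows with the split feature missing go to the child that
    received more observed training rows (ties to the left).  Ties in
    impurity decrease break toward the lower feature index, then the lower
    threshold.
    """

    def __init__(self, max_depth: int = 3, min_leaf: int = 10) -> None:
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.root: Optional[_TreeNode] = None
        self.leaves: list[_TreeNode] = []

    def fit(self, X: np.ndarray, y: np.ndarray) -> "DecisionTree":
        self.leaves = []
        self.root = self._grow(X, y, depth=0)
        for i, leaf in enumerate(self.leaves):
            leaf.leaf_id = i
        return self

    def _grow(self, X: np.ndarray, y: np.ndarray, depth: int) -> _TreeNode:
        n = len(y)
        node = _TreeNode(n=n, n_pos=int(y.sum()))
        if depth >= self.max_depth or n < 2 * self.min_leaf or node.n_pos in (0, n):
            self.leaves.append(node)
            return node
        best = None  # (impurity_decrease, -feature, -threshold) max
        parent_imp = _gini(node.n_pos, n) * n
        for f in range(X.shape[1]):
            col = X[:, f]
            obs = ~np.isnan(col)
            n_obs = int(obs.sum())
            if n_obs < 2:
                continue
            n_miss = n - n_obs
            pos_miss = float(y[~obs].sum())
            order = np.argsort(col[obs], kind="stable")
            v_sorted = col[obs][order]
            y_sorted = y[obs][order]
            distinct = np.nonzero(np.diff(v_sorted) > 0)[0]  # split after i
            if distinct.size == 0:
                continue
            cum_pos = np.cumsum(y_sorted)
            thresholds = (v_sorted[distinct] + v_sorted[distinct + 1]) / 2.0
            nl_obs = distinct + 1
            nr_obs = n_obs - nl_obs
            missing_left = nl_obs >= nr_obs
            nl = nl_obs + missing_left * n_miss
            nr = n - nl
            pos_l = cum_pos[distinct] + missing_left * pos_miss
            pos_r = (node.n_pos) - pos_l
            valid = (nl >= self.min_leaf) & (nr >= self.min_leaf)
            if not valid.any():
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                imp = (2.0 * pos_l * (nl - pos_l) / nl
                       + 2.0 * pos_r * (nr - pos_r) / nr)
            dec = np.where(valid, parent_imp - imp, -np.inf)
            # ties break toward the lower threshold: first argmax suffices
            i = int(np.argmax(dec))
            key = (float(dec[i]), -f, -float(thresholds[i]))
            if dec[i] > -np.inf and (best is None or key > best[0]):
                thr = float(thresholds[i])
                left = (obs & (col <= thr)) | (~obs if missing_left[i] else
                                               np.zeros(n, bool))
                best = (key, f, thr, bool(missing_left[i]), left)
        if best is None or best[0][0] <= 1e-12:
            self.leaves.append(node)
            return node
        _, f, thr, missing_left, left_mask = best
        node.feature = f
        node.threshold = thr
        node.missing_left = missing_left
        node.left = self._grow(X[left_mask], y[left_mask], depth + 1)
        node.right = self._grow(X[~left_mask], y[~left_mask], depth + 1)
        return node

    def apply(self, X: np.ndarray) -> np.ndarray:
        """Leaf index for each row."""
        out = np.empty(len(X), dtype=int)
        for i, row in enumerate(X):
            node = self.root
            while not node.is_leaf:
                v = row[node.feature]
                if np.isnan(v):
                    node = node.left if node.missing_left else node.right
                elif v <= node.threshold:
                    node = node.left
                else:
                    node = node.right
            out[i] = node.leaf_id
        return out

    def paths(self) -> list[tuple[list[tuple[str, str, float]], _TreeNode]]:
        """(condition-path, leaf) pairs; conditions are (feature, op, thr)."""
        result = []

        def walk(node, conds):
            if node.is_leaf:
                result.append((conds, node))
                return
            fname = STEP3_FEATURES[node.feature]
            walk(node.left, conds + [(fname, "<=", node.threshold)])
            walk(node.right, conds + [(fname, ">", node.threshold)])

        if self.root is not None:
            walk(self.root, [])
        return result


@dataclass
class DerivedTriageModel:
    """A derived model: step A/B thresholds plus the fitted step-C tree.

    ``spec`` carries the grid-search thresholds for steps A and B and the
    best-effort read-off of the tree's top splits into the fixed step-C rule
    shape; classification at C uses the tree itself.
    """

    spec: TriageModelSpec
    step_c_tree: Optional[DecisionTree] = None
    leaf_labels: dict[int, Decision] = field(default_factory=dict)
    degenerate: bool = False

    def classify_c(self, cl_a, cl_b, cl_c) -> Decision:
        if self.step_c_tree is None:
            return classify_C(cl_a, cl_b, cl_c, self.spec)
        feats = _step3_features_row(cl_a, cl_b, cl_c)
        leaf = int(self.step_c_tree.apply(feats[None, :])[0])
        return self.leaf_labels.get(leaf, Decision.HIGH_RISK)


def _step3_features_row(cl_a, cl_b, cl_c) -> np.ndarray:
    def safe_delta(e, l):
        if e is None or l is None or np.isnan(e) or np.isnan(l):
            return np.nan
        return pct_delta_cl(e, l)

    vals = [np.nan if v is None else float(v) for v in (cl_a, cl_b, cl_c)]
    return np.array(
        vals + [safe_delta(vals[0], vals[1]), safe_delta(vals[1], vals[2]),
                safe_delta(vals[0], vals[2])]
    )


def _step3_matrix(df: pd.DataFrame) -> np.ndarray:
    return df[list(STEP3_FEATURES)].to_numpy(dtype=float)


def _read_off_c_rules(tree: DecisionTree, labels: dict[int, Decision],
                      base: TriageModelSpec) -> dict:
    """Best-effort mapping of tree paths onto the fixed step-C rule shape."""
    updates: dict = {}
    for conds, leaf in tree.paths():
        if labels.get(leaf.leaf_id) is not Decision.HIGH_RISK:
            continue
        names = [c[0] for c in conds]
        lookup = {(c[0], c[1]): c[2] for c in conds}
        if names == ["cl_c"] and ("cl_c", "<=") in lookup:
            updates["c_rule2_c_le"] = round(lookup[("cl_c", "<=")])
        elif set(names) == {"cl_a", "d_ac"} and ("cl_a", "<=") in lookup \
                and ("d_ac", ">") in lookup:
            updates["c_rule1_a_lt"] = round(lookup[("cl_a", "<=")]) + 1
            updates["c_rule1_delta_ge"] = round(lookup[("d_ac", ">")])
            updates["c_rule1_delta_interval"] = "A-C"
        elif set(names) == {"cl_a", "cl_b"} and ("cl_a", ">") in lookup \
                and ("cl_b", "<=") in lookup:
            updates["c_rule3_a_ge"] = round(lookup[("cl_a", ">")]) + 1
            updates["c_rule3_b_lt"] = round(lookup[("cl_b", "<=")]) + 1
    return updates


def derive_triage_model(
    cohort: Union[Sequence[PregnancyRecord], pd.DataFrame],
    constraints: DerivationConstraints = DerivationConstraints(),
) -> tuple[DerivedTriageModel, dict]:
    """Derive a 3-step model from a labelled cohort.

    Steps 1 and 2 are exhaustive integer-grid searches maximising resolved
    records under the cumulative false-low-risk cap; step 3 fits the
    deterministic tree on the remaining records and labels leaves DISCHARGE
    greedily (lowest high-risk fraction first) while the cumulative cap
    holds.  Returns the model and a derivation report.
    """
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    y = df["group2"].to_numpy(dtype=bool)
    total_g2 = int(y.sum())
    cl_a = df["cl_a"].to_numpy(dtype=float)
    report: dict = {"n": len(df), "n_group2": total_g2}

    s1 = _search_step1(cl_a, y, constraints, total_g2)
    if s1 is None:
        # No feasible pair resolves anyone: return a maximally conservative
        # model (discharges nobody, flags everyone at the terminal visit).
        report["warning"] = "no feasible step-1 thresholds; degenerate model"
        degenerate_spec = TriageModelSpec(
            a_high_lt=5.0, a_low_ge=60.0,
            b_high_cl_lt=5.0, b_high_delta_ge=100.0,
            b_low_cl_ge=60.0, b_low_delta_lt=0.0, b_low_rule="and",
            c_rule2_c_le=60.0,
        )
        model = DerivedTriageModel(spec=degenerate_spec, degenerate=True)
        return model, report
    a_high, a_low, disc_n, disc_g2 = s1
    report["step1"] = {"a_high_lt": a_high, "a_low_ge": a_low,
                       "discharged": disc_n, "discharged_group2": disc_g2}

    obs_a = ~np.isnan(cl_a)
    resolved1 = obs_a & ((cl_a < a_high) | (cl_a >= a_low))
    rem1 = df[~resolved1]
    s2 = _search_step2(
        rem1["cl_b"].to_numpy(float), rem1["d_ab"].to_numpy(float),
        rem1["group2"].to_numpy(bool), constraints, total_g2, disc_n, disc_g2,
    )
    b_low_rule = "or"
    if s2 is None:
        # conservative fallback: an AND low rule that fires for ~nobody
        b_high_cl, b_high_d = constraints.cl_grid[0], constraints.pct_grid[1]
        b_low_cl, b_low_d = constraints.cl_grid[1], constraints.pct_grid[0]
        b_low_rule = "and"
        disc_n2 = disc_g2_2 = 0
        report["step2"] = {"warning": "no feasible step-2 thresholds"}
    else:
        b_high_cl, b_high_d, b_low_cl, b_low_d, disc_n2, disc_g2_2 = s2
        report["step2"] = {
            "b_high_cl_lt": b_high_cl, "b_high_delta_ge": b_high_d,
            "b_low_cl_ge": b_low_cl, "b_low_delta_lt": b_low_d,
            "discharged": disc_n2, "discharged_group2": disc_g2_2,
        }

    spec_kwargs = dict(
        a_high_lt=float(a_high), a_low_ge=float(a_low),
        b_high_cl_lt=float(b_high_cl), b_high_delta_ge=float(b_high_d),
        b_low_cl_ge=float(b_low_cl), b_low_delta_lt=float(b_low_d),
        b_low_rule=b_low_rule,
    )
    interim = TriageModelSpec(**spec_kwargs)

    cl_b = rem1["cl_b"].to_numpy(float)
    d_ab = rem1["d_ab"].to_numpy(float)
    with np.errstate(invalid="ignore"):
        high2 = (cl_b < b_high_cl) | (d_ab >= b_high_d)
        low2 = (cl_b >= b_low_cl) | (d_ab < b_low_d)
    resolved2 = high2 | (low2 & ~high2)
    rem2 = rem1[~resolved2]

    carried_n = disc_n + disc_n2
    carried_g2 = disc_g2 + disc_g2_2
    tree = None
    leaf_labels: dict[int, Decision] = {}
    if len(rem2) >= 2 * constraints.tree_min_leaf:
        tree = DecisionTree(constraints.tree_max_depth, constraints.tree_min_leaf)
        X3 = _step3_matrix(rem2)
        y3 = rem2["group2"].to_numpy(dtype=float)
        tree.fit(X3, y3)
        # greedy leaf labelling under the cumulative cap
        order = sorted(tree.leaves, key=lambda lf: (lf.n_pos / lf.n, -lf.n, lf.leaf_id))
        run_n, run_g2 = carried_n, carried_g2
        for leaf in order:
            if _feasible(run_g2 + leaf.n_pos, run_n + leaf.n, total_g2, constraints):
                leaf_labels[leaf.leaf_id] = Decision.DISCHARGE
                run_n += leaf.n
                run_g2 += leaf.n_pos
            else:
                leaf_labels[leaf.leaf_id] = Decision.HIGH_RISK
        spec_kwargs.update(_read_off_c_rules(tree, leaf_labels, interim))
        report["step3"] = {
            "n_records": int(len(rem2)),
            "n_leaves": len(tree.leaves),
            "discharge_leaves": sum(
                1 for v in leaf_labels.values() if v is Decision.DISCHARGE
            ),
        }
    else:
        report["step3"] = {"n_records": int(len(rem2)),
                           "warning": "too few records for a tree"}

    try:
        spec = TriageModelSpec(**spec_kwargs)
    except ValueError:
        spec = interim  # read-off produced an inconsistent rule set
        report["step3"]["readoff_rejected"] = True
    model = DerivedTriageModel(spec=spec, step_c_tree=tree, leaf_labels=leaf_labels)
    return model, report


def evaluate_model(df: pd.DataFrame, model) -> dict:
    """Sensitivity for high-risk (GROUP2) records and the false-low-risk rate
    (GROUP2 members among low-risk calls) of a model on a labelled frame."""
    finals = []
    for _, row in df.iterrows():
        out = run_triage(row.to_dict(), model)
        finals.append(out.final)
    finals = np.array([f.value for f in finals])
    y = df["group2"].to_numpy(bool)
    low = np.isin(finals, [s.value for s in LOW_RISK_FINALS])
    high = finals == FinalStatus.HIGH_RISK.value
    n_low = int(low.sum())
    return {
        "n": len(df),
        "n_group2": int(y.sum()),
        "n_low_risk_calls": n_low,
        "n_high_risk_calls": int(high.sum()),
        "sensitivity": float(high[y].mean()) if y.any() else float("nan"),
        "false_low_risk_rate": float(y[low].mean()) if n_low else 0.0,
    }


def leave_one_hospital_out(
    records: Union[Sequence[PregnancyRecord], pd.DataFrame],
    constraints: DerivationConstraints = DerivationConstraints(),
) -> list[dict]:
    """Site-wise cross-validation: derive on all-but-one hospital, evaluate
    on the held-out site.  Requires >= 2 distinct hospitals."""
    df = records if isinstance(records, pd.DataFrame) else cohort_to_frame(records)
    hospitals = sorted(df["hospital"].unique())
    if len(hospitals) < 2:
        raise ValueError("leave-one-hospital-out validation needs >= 2 hospitals")
    folds = []
    for h in hospitals:
        train = df[df["hospital"] != h]
        test = df[df["hospital"] == h]
        model, report = derive_triage_model(train, constraints)
        ev = evaluate_model(test, model)
        folds.append({"hospital": h, "model": model, "derivation": report, **ev})
    return folds


# ===========================================================================
# scikit-learn style estimator
# ===========================================================================

from sklearn.base import BaseEstimator  # noqa: E402


class TriageClassifier(BaseEstimator):
    """Sequential CL triage as an sklearn-style estimator.

    Parameters
    ----------
    model : TriageModelSpec or None
        Fixed threshold set; ``None`` derives the thresholds in ``fit``
        (which then requires ``y``, the binary high-risk labels).
    max_false_low_risk_rate, constraint_scope, cl_grid, pct_grid,
    tree_max_depth, tree_min_leaf :
        Derivation constraints (ignored when ``model`` is given).

    Attributes
    ----------
    model_ : TriageModelSpec or DerivedTriageModel
    report_ : dict (derivation report; empty for a fixed model)
    classes_ : ndarray of final statuses
    """

    def __init__(self, model: Optional[TriageModelSpec] = None,
                 max_false_low_risk_rate: float = 0.05,
                 constraint_scope: str = "discharges",
                 cl_grid: tuple[int, int] = (10, 50),
                 pct_grid: tuple[int, int] = (0, 40),
                 tree_max_depth: int = 3,
                 tree_min_leaf: int = 10) -> None:
        self.model = model
        self.max_false_low_risk_rate = max_false_low_risk_rate
        self.constraint_scope = constraint_scope
        self.cl_grid = cl_grid
        self.pct_grid = pct_grid
        self.tree_max_depth = tree_max_depth
        self.tree_min_leaf = tree_min_leaf

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            df = X.copy()
        else:
            df = pd.DataFrame(np.asarray(X, dtype=float),
                              columns=["cl_a", "cl_b", "cl_c"])
        for col in ("cl_a", "cl_b", "cl_c"):
            if col not in df:
                raise ValueError(f"X must carry column {col}")
        for d, (e, l) in (("d_ab", ("cl_a", "cl_b")), ("d_bc", ("cl_b", "cl_c")),
                          ("d_ac", ("cl_a", "cl_c"))):
            if d not in df:
                df[d] = 100.0 * (df[e] - df[l]) / df[e]
        return df

    def fit(self, X, y=None):
        df = self._as_frame(X)
        if self.model is not None:
            self.model_ = self.model
            self.report_ = {}
        else:
            if y is None:
                raise ValueError("y (binary high-risk labels) required to derive a model")
            df = df.copy()
            df["group2"] = np.asarray(y, dtype=bool)
            constraints = DerivationConstraints(
                max_false_low_risk_rate=self.max_false_low_risk_rate,
                cl_grid=self.cl_grid, pct_grid=self.pct_grid,
                tree_max_depth=self.tree_max_depth,
                tree_min_leaf=self.tree_min_leaf,
                constraint_scope=self.constraint_scope,
            )
            self.model_, self.report_ = derive_triage_model(df, constraints)
        self.classes_ = np.array([s.value for s in FinalStatus])
        return self

    def predict(self, X) -> np.ndarray:
        """Final status per row (HIGH_RISK / DISCHARGE / COMPLETED)."""
        if not hasattr(self, "model_"):
            raise ValueError("TriageClassifier is not fitted")
        df = self._as_frame(X)
        return np.array(
            [run_triage(row.to_dict(), self.model_).final.value
             for _, row in df.iterrows()]
        )

    def predict_outcomes(self, X) -> pd.DataFrame:
        """Full per-row outcome frame (decisions per visit, scans used)."""
        if not hasattr(self, "model_"):
            raise ValueError("TriageClassifier is not fitted")
        df = self._as_frame(X)
        rows = []
        for _, row in df.iterrows():
            out = run_triage(row.to_dict(), self.model_)
            rows.append(
                {
                    "decision_A": out.decisions.get(Timepoint.A, Decision.CONTINUE).value,
                    "decision_B": out.decisions[Timepoint.B].value
                    if Timepoint.B in out.decisions else "",
                    "decision_C": out.decisions[Timepoint.C].value
                    if Timepoint.C in out.decisions else "",
                    "final": out.final.value,
                    "scans_used": out.scans_used,
                }
            )
        return pd.DataFrame(rows, index=df.index)
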