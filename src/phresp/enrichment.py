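"""Gene-set enrichment by functional class scoring, over-representation, and
the unidirectional gene-set criterion, with per-method FDR control and a
composite at-least-one-method call.

Three complementary views of the same contrast are combined:

* **FCS** — the in-set SLFDR scores are aggregated by a Wilcoxon rank-sum
  statistic against the out-of-set scores; significance is assessed by *gene
  sampling*: random member sets of the same size are drawn from the universe
  and the two-sided empirical p-value (+1 corrected) is taken from that null.
  Under the printed SLFDR convention (significant upregulation -> negative
  score) a shift toward negative ranks means an upregulation tendency, i.e.
  "enriched".
* **ORA** — two 2x2 chi-square tests per set ask whether the proportions of
  up- and of down-regulated DEGs inside the set exceed those outside; the two
  directions are tested separately so a set can be called "both".
* **UGS** — a deterministic criterion flagging sets whose DEGs are
  *exclusively* upregulated (enriched) or exclusively downregulated
  (depleted), regardless of their proportion in the set; no p-value exists.

Per-method raw calls carry a *candidate* direction (the sign of the effect);
:func:`adjust_and_combine` applies Benjamini-Hochberg per method x direction
family, keeps directions significant at the threshold (UGS calls pass
through unchanged), and unions the per-method calls into composite
enriched/depleted flags with the supporting methods recorded.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "EnrichmentCall",
    "CompositeCall",
    "GeneSamplingNull",
    "fcs",
    "ora",
    "ugs",
    "adjust_and_combine",
    "run_enrichment",
]

ENRICH_ALPHA_DEFAULT = 0.01
N_PERM_DEFAULT = 10_000
UGS_MIN_DEGS_DEFAULT = 2

_EPS = 1e-9


@dataclass(frozen=True)
class EnrichmentCall:
    """One method's verdict on one gene set.

    Before FDR adjustment ``direction`` is the candidate direction implied by
    the effect sign; after :func:`adjust_and_combine` it is ``none`` unless
    the method's FDR cleared the threshold (UGS is deterministic and carries
    no p/fdr).  ORA additionally records the per-direction raw p-values.
    """

    set_id: str
    method: str  # FCS | ORA | UGS
    direction: str  # enriched | depleted | both | none
    statistic: float | None
    p: float | None
    fdr: float | None
    n_deg_up: int
    n_deg_down: int
    n_set: int
    p_enriched: float | None = None
    p_depleted: float | None = None


@dataclass(frozen=True)
class CompositeCall:
    """Union over methods: a set is affected if any method called it."""

    set_id: str
    enriched: bool
    depleted: bool
    supporting_enriched: tuple[str, ...]
    supporting_depleted: tuple[str, ...]


class GeneSamplingNull:
    """Gene-sampling null distributions of the rank-sum statistic, shared per universe.

    For one vector of gene-level scores, the null of the in-set rank sum W
    depends only on the set size k, so the per-size null samples are cached
    and reused by every set of that size.  Draws for size k are seeded by
    (seed, k), making each null independent of query order.
    """

    def __init__(self, scores: np.ndarray, n_perm: int = N_PERM_DEFAULT, seed: int | None = None):
        self.scores = np.asarray(scores, dtype=float)
        if self.scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        self.n = self.scores.size
        self.ranks = stats.rankdata(self.scores)
        self.n_perm = int(n_perm)
        self.seed = seed
        self._cache: dict[int, np.ndarray] = {}

    def expected_w(self, k: int) -> float:
        return k * (self.n + 1) / 2.0

    def null_w(self, k: int, block: int = 512) -> np.ndarray:
        """``n_perm`` rank-sum draws for random member sets of size ``k``."""
        if not 1 <= k < self.n:
            raise ValueError(f"set size {k} must be in [1, {self.n - 1}]")
        if k not in self._cache:
            rng = np.random.default_rng(
                self.seed if self.seed is None else [int(self.seed), k]
            )
            out = np.empty(self.n_perm)
            done = 0
            while done < self.n_perm:
                m = min(block, self.n_perm - done)
                keys = rng.random((m, self.n))
                idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
                out[done : done + m] = self.ranks[idx].sum(axis=1)
                done += m
            self._cache[k] = out
        return self._cache[k]

    def exact_w(self, k: int) -> np.ndarray:
        """Rank sums of *all* C(n, k) member subsets (exhaustive enumeration)."""
        combos = itertools.combinations(range(self.n), k)
        return np.fromiter(
            (self.ranks[list(c)].sum() for c in combos), dtype=float, count=math.comb(self.n, k)
        )


def _in_set_mask(scored: pd.DataFrame, set_members: Iterable[str]) -> np.ndarray:
    members = frozenset(set_members)
    mask = scored.index.isin(members)
    return np.asarray(mask, dtype=bool)


def _deg_counts(scored: pd.DataFrame, mask: np.ndarray) -> tuple[int, int]:
    labels = scored["deg_label"].to_numpy()
    return int(np.sum(labels[mask] == "up")), int(np.sum(labels[mask] == "down"))


def fcs(
    scored: pd.DataFrame,
    set_members: Iterable[str],
    n_perm: int = N_PERM_DEFAULT,
    seed: int | None = None,
    engine: GeneSamplingNull | None = None,
    mode: str = "sampling",
) -> EnrichmentCall:
    """Functional class scoring of one gene set by gene-sampling rank statistics.

    The global statistic is the Wilcoxon rank-sum (sum of pooled ranks of the
    in-set SLFDR values).  ``mode="sampling"`` (default) uses the empirical
    gene-sampling null with the +1 correction — switching automatically to
    exhaustive subset enumeration when C(universe, set size) <= n_perm;
    ``mode="asymptotic"`` uses the normal-approximation Wilcoxon p instead.
    """
    if mode not in ("sampling", "asymptotic"):
        raise ValueError(f"unknown mode {mode!r}")
    mask = _in_set_mask(scored, set_members)
    k = int(mask.sum())
    n = len(scored)
    if k == 0:
        raise ValueError("gene set is empty after universe restriction")
    if k == n:
        raise ValueError("gene set equals the universe: no out-of-set genes to compare")
    if engine is None:
        engine = GeneSamplingNull(scored["slfdr"].to_numpy(), n_perm=n_perm, seed=seed)
    w_obs = float(engine.ranks[mask].sum())
    expected = engine.expected_w(k)
    delta = w_obs - expected

    if mode == "asymptotic":
        scores = scored["slfdr"].to_numpy(dtype=float)
        res = stats.mannwhitneyu(
            scores[mask], scores[~mask], alternative="two-sided",
            method="asymptotic", use_continuity=False,
        )
        p = float(res.pvalue)
    elif math.comb(n, k) <= engine.n_perm:
        null = engine.exact_w(k)
        hits = int(np.sum(np.abs(null - expected) >= abs(delta) - _EPS))
        p = hits / null.size
    else:
        null = engine.null_w(k)
        hits = int(np.sum(np.abs(null - expected) >= abs(delta) - _EPS))
        p = (1 + hits) / (engine.n_perm + 1)

    # printed SLFDR convention: negative shift = upregulation tendency = enriched
    direction = "enriched" if delta < 0 else "depleted" if delta > 0 else "none"
    up, down = _deg_counts(scored, mask)
    return EnrichmentCall(
        set_id="", method="FCS", direction=direction, statistic=w_obs, p=p,
        fdr=None, n_deg_up=up, n_deg_down=down, n_set=k,
    )


def _chi2_2x2(in_hit: int, in_miss: int, out_hit: int, out_miss: int) -> float:
    """Two-sided chi-square p for a 2x2 table, without continuity correction.

    Degenerate tables (a zero margin makes an expected cell 0) yield p = 1
    with a warning.
    """
    table = np.array([[in_hit, in_miss], [out_hit, out_miss]], dtype=float)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        warnings.warn("degenerate 2x2 table (zero margin): p set to 1", stacklevel=3)
        return 1.0
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def ora(scored: pd.DataFrame, set_members: Iterable[str]) -> EnrichmentCall:
    """Over-representation of up- and down-regulated DEGs in one gene set.

    Two separate 2x2 chi-square tests compare the in-set vs out-of-set
    proportions of up-DEGs and of down-DEGs.  The candidate direction is
    ``enriched`` when the in-set up-proportion exceeds the out-of-set one (and
    likewise ``depleted`` for down); both can hold at once.  ``p`` records the
    smaller of the two raw p-values; the per-direction raw p-values are kept
    in ``p_enriched`` / ``p_depleted`` for the direction-wise FDR families.
    """
    mask = _in_set_mask(scored, set_members)
    k = int(mask.sum())
    n = len(scored)
    if k == 0:
        raise ValueError("gene set is empty after universe restriction")
    if k >= n:
        raise ValueError("universe must be larger than the gene set")
    labels = scored["deg_label"].to_numpy()
    in_up, in_down = _deg_counts(scored, mask)
    total_up = int(np.sum(labels == "up"))
    total_down = int(np.sum(labels == "down"))
    out_n = n - k
    out_up, out_down = total_up - in_up, total_down - in_down

    p_up = _chi2_2x2(in_up, k - in_up, out_up, out_n - out_up)
    p_down = _chi2_2x2(in_down, k - in_down, out_down, out_n - out_down)
    cand_up = in_up / k > out_up / out_n
    cand_down = in_down / k > out_down / out_n
    if cand_up and cand_down:
        direction = "both"
    elif cand_up:
        direction = "enriched"
    elif cand_down:
        direction = "depleted"
    else:
        direction = "none"
    return EnrichmentCall(
        set_id="", method="ORA", direction=direction,
        statistic=None, p=min(p_up, p_down), fdr=None,
        n_deg_up=in_up, n_deg_down=in_down, n_set=k,
        p_enriched=p_up,
        p_depleted=p_down,
    )


def ugs(
    scored: pd.DataFrame,
    set_members: Iterable[str],
    min_degs: int = UGS_MIN_DEGS_DEFAULT,
) -> EnrichmentCall:
    """Unidirectional gene-set call: all in-set DEGs share one direction.

    ``enriched`` if the set holds at least ``min_degs`` up-DEGs and no
    down-DEG; ``depleted`` symmetrically.  Deterministic — no p-value.
    """
    mask = _in_set_mask(scored, set_members)
    k = int(mask.sum())
    up, down = _deg_counts(scored, mask)
    if up >= min_degs and down == 0:
        direction = "enriched"
    elif down >= min_degs and up == 0:
        direction = "depleted"
    else:
        direction = "none"
    return EnrichmentCall(
        set_id="", method="UGS", direction=direction, statistic=float(up - down),
        p=None, fdr=None, n_deg_up=up, n_deg_down=down, n_set=k,
    )


def _bh(pvals: Sequence[float]) -> np.ndarray:
    if len(pvals) == 0:
        return np.array([])
    return multipletests(list(pvals), method="fdr_bh")[1]


def adjust_and_combine(
    calls: Mapping[str, Sequence[EnrichmentCall]],
    alpha: float = ENRICH_ALPHA_DEFAULT,
) -> tuple[list[EnrichmentCall], list[CompositeCall]]:
    """BH-adjust per method x direction and union the methods per set.

    ``calls`` maps method name (FCS/ORA/UGS) to that method's raw calls over
    one family of sets (one strain x contrast x set type).  FCS p-values are
    adjusted within the family of their candidate direction; ORA contributes
    its up-test p to the enriched family and its down-test p to the depleted
    family; UGS calls pass through unchanged.  Returns the adjusted calls and
    the composite per-set calls (at least one supporting method per flag).
    """
    known = {"FCS", "ORA", "UGS"}
    stray = set(calls) - known
    if stray:
        raise ValueError(f"unknown methods: {sorted(stray)}")
    missing = known - set(calls)
    if missing:
        warnings.warn(f"combining without methods {sorted(missing)}", stacklevel=2)

    adjusted: list[EnrichmentCall] = []
    # per-set directional verdicts: set_id -> direction -> set of methods
    verdicts: dict[str, dict[str, set[str]]] = {}

    def record(set_id: str, direction: str, method: str) -> None:
        verdicts.setdefault(set_id, {"enriched": set(), "depleted": set()})
        verdicts[set_id][direction].add(method)

    for call in calls.get("UGS", []):
        adjusted.append(call)
        verdicts.setdefault(call.set_id, {"enriched": set(), "depleted": set()})
        if call.direction in ("enriched", "depleted"):
            record(call.set_id, call.direction, "UGS")

    fcs_calls = list(calls.get("FCS", []))
    for direction in ("enriched", "depleted"):
        group = [c for c in fcs_calls if c.direction == direction]
        fdrs = _bh([c.p for c in group])
        for call, q in zip(group, fdrs):
            keep = q < alpha
            adjusted.append(replace(call, fdr=float(q), direction=direction if keep else "none"))
            verdicts.setdefault(call.set_id, {"enriched": set(), "depleted": set()})
            if keep:
                record(call.set_id, direction, "FCS")
    for call in fcs_calls:
        if call.direction == "none":
            adjusted.append(call)
            verdicts.setdefault(call.set_id, {"enriched": set(), "depleted": set()})

    ora_calls = list(calls.get("ORA", []))
    ora_sig: dict[str, set[str]] = {c.set_id: set() for c in ora_calls}
    ora_q: dict[str, dict[str, float]] = {c.set_id: {} for c in ora_calls}
    for direction, attr in (("enriched", "p_enriched"), ("depleted", "p_depleted")):
        group = [c for c in ora_calls if getattr(c, attr) is not None]
        fdrs = _bh([getattr(c, attr) for c in group])
        for call, q in zip(group, fdrs):
            ora_q[call.set_id][direction] = float(q)
            # BH family = every set's per-direction p; candidacy (in-set
            # proportion actually exceeding the out-of-set one) gates the call
            if q < alpha and call.direction in (direction, "both"):
                ora_sig[call.set_id].add(direction)
                record(call.set_id, direction, "ORA")
    for call in ora_calls:
        sig = ora_sig[call.set_id]
        qs = ora_q[call.set_id]
        if len(sig) == 2:
            direction = "both"
        elif sig:
            direction = next(iter(sig))
        else:
            direction = "none"
        q_report = min((qs[d] for d in sig), default=min(qs.values(), default=None))
        adjusted.append(replace(call, fdr=q_report, direction=direction))
        verdicts.setdefault(call.set_id, {"enriched": set(), "depleted": set()})

    composites = [
        CompositeCall(
            set_id=sid,
            enriched=bool(v["enriched"]),
            depleted=bool(v["depleted"]),
            supporting_enriched=tuple(sorted(v["enriched"])),
            supporting_depleted=tuple(sorted(v["depleted"])),
        )
        for sid, v in sorted(verdicts.items())
    ]
    return adjusted, composites


def run_enrichment(
    scored: pd.DataFrame,
    sets: Mapping[str, Iterable[str]],
    methods: Sequence[str] = ("FCS", "ORA", "UGS"),
    alpha: float = ENRICH_ALPHA_DEFAULT,
    n_perm: int = N_PERM_DEFAULT,
    seed: int | None = None,
    ugs_min_degs: int = UGS_MIN_DEGS_DEFAULT,
    fcs_mode: str = "sampling",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every set of one family with the requested methods and combine.

    ``scored`` is the :func:`phresp.scoring.call_degs` output restricted to
    one gene universe; ``sets`` maps set id to members (already restricted).
    Returns (per-method calls frame, composite calls frame).  One
    :class:`GeneSamplingNull` engine is shared by all FCS calls so equal-size
    sets reuse the same null draws.
    """
    methods = [m.upper() for m in methods]
    raw: dict[str, list[EnrichmentCall]] = {}
    if "FCS" in methods:
        engine = GeneSamplingNull(scored["slfdr"].to_numpy(), n_perm=n_perm, seed=seed)
        raw["FCS"] = [
            replace(fcs(scored, members, engine=engine, mode=fcs_mode), set_id=sid)
            for sid, members in sets.items()
        ]
    if "ORA" in methods:
        raw["ORA"] = [replace(ora(scored, m), set_id=sid) for sid, m in sets.items()]
    if "UGS" in methods:
        raw["UGS"] = [
            replace(ugs(scored, m, min_degs=ugs_min_degs), set_id=sid)
            for sid, m in sets.items()
        ]
    adjusted, composites = adjust_and_combine(raw, alpha=alpha)
    calls_df = pd.DataFrame([vars(c) for c in adjusted])
    comp_df = pd.DataFrame(
        [
            {
                "set_id": c.set_id,
                "enriched": c.enriched,
                "depleted": c.depleted,
                "supporting_enriched": ",".join(c.supporting_enriched),
                "supporting_depleted": ",".join(c.supporting_depleted),
            }
            for c in composites
        ]
    )
    return calls_df, comp_df
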