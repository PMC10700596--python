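"""Control calculations validating the docking setup.

Property-matched decoy generation (DUDE-Z-style windows around each
ligand), charge-stratified "extrema" challenge sets, and the enrichment
metrics used to judge a grid configuration: ROC AUC and the adjusted
semilog AUC (early-enrichment area on a log10 false-positive-rate axis,
minus the random baseline, so random scoring gives exactly 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .libprep import CompoundRecord, tanimoto


# ---------------------------------------------------------------------------
# Property-matched decoys
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecoyWindows:
    """DUDE-Z-style matching windows around each ligand's properties."""

    mwt: float = 25.0            # ± amu
    clogp: float = 1.0           # ±
    rotatable_bonds: int = 2     # ±
    hbd: int = 2                 # ±
    hba: int = 2                 # ±
    match_charge: bool = True
    tc_cap: float = 0.35         # decoys must be dissimilar to their ligand


@dataclass
class DecoySet:
    per_ligand: dict[str, list[CompoundRecord]]
    windows: DecoyWindows
    shortfalls: dict[str, int]   # ligand id -> missing count

    @property
    def n_total(self) -> int:
        return sum(len(v) for v in self.per_ligand.values())


def in_windows(ligand: CompoundRecord, cand: CompoundRecord,
               w: DecoyWindows) -> bool:
    """All property-window predicates (inclusive boundaries)."""
    return (
        abs(cand.mwt - ligand.mwt) <= w.mwt
        and abs(cand.clogp - ligand.clogp) <= w.clogp
        and abs(cand.rotatable_bonds - ligand.rotatable_bonds) <= w.rotatable_bonds
        and abs(cand.hbd - ligand.hbd) <= w.hbd
        and abs(cand.hba - ligand.hba) <= w.hba
        and (not w.match_charge or cand.net_charge == ligand.net_charge)
    )


def make_property_matched_decoys(
    ligands: Sequence[CompoundRecord],
    pool: Sequence[CompoundRecord],
    n_per_ligand: int,
    windows: DecoyWindows = DecoyWindows(),
) -> DecoySet:
    """For each ligand, select the ``n_per_ligand`` most topologically
    dissimilar pool members that fall inside every property window and
    below the similarity cap (ties broken by pool order).

    A ligand's own structure can never be its decoy (canonical-SMILES
    inequality enforced on top of the Tc cap); shortfalls are logged, not
    fatal.
    """
    if not pool:
        raise ValueError("decoy pool is empty")
    per_ligand: dict[str, list[CompoundRecord]] = {}
    shortfalls: dict[str, int] = {}
    for lig in ligands:
        candidates = []
        for j, cand in enumerate(pool):
            if cand.smiles == lig.smiles:
                continue
            if not in_windows(lig, cand, windows):
                continue
            tc = tanimoto(lig.fingerprint, cand.fingerprint)
            if tc >= windows.tc_cap:
                continue
            candidates.append((tc, j, cand))
        candidates.sort(key=lambda t: (t[0], t[1]))  # most dissimilar first
        chosen = [c for _, _, c in candidates[:n_per_ligand]]
        per_ligand[lig.id] = chosen
        if len(chosen) < n_per_ligand:
            shortfalls[lig.id] = n_per_ligand - len(chosen)
    return DecoySet(per_ligand, windows, shortfalls)


# ---------------------------------------------------------------------------
# Extrema challenge set
# ---------------------------------------------------------------------------

def make_extrema_set(
    pool: Sequence[CompoundRecord],
    composition: dict[str, int],
    seed: int = 0,
) -> list[CompoundRecord]:
    """Stratified deterministic sample per net-charge class.

    ``composition`` maps charge-class labels ("+1", "0", "-1", "<=-2") to
    requested counts; a class short of members raises ``ValueError``
    naming it.  Class labels are retained on the records.
    """
    rng = np.random.default_rng(seed)
    by_class: dict[str, list[CompoundRecord]] = {}
    for r in pool:
        by_class.setdefault(r.charge_class, []).append(r)
    out: list[CompoundRecord] = []
    for cls, n in composition.items():
        members = by_class.get(cls, [])
        if len(members) < n:
            raise ValueError(
                f"charge class {cls!r} has only {len(members)} pool members, "
                f"{n} requested"
            )
        idx = rng.choice(len(members), size=n, replace=False)
        out.extend(members[i] for i in sorted(idx))
    return out


# ---------------------------------------------------------------------------
# Enrichment metrics
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentResult:
    roc_points: np.ndarray       # (k, 2): FPR, TPR, monotone nondecreasing
    auc: float
    adjusted_logauc: float
    n_ligands: int
    n_decoys: int

    def summary(self) -> str:
        return (
            "Enrichment metrics\n"
            "==================\n"
            f"ligands / decoys   {self.n_ligands} / {self.n_decoys}\n"
            f"ROC AUC            {self.auc:.4f}\n"
            f"adjusted logAUC    {self.adjusted_logauc:.4f}"
        )


def _roc_points(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """ROC by descending docking favorability (ascending energy score);
    tied scores advance as one block, which averages over tie orderings."""
    order = np.argsort(scores, kind="stable")
    s = scores[order]
    y = labels[order]
    n_pos = int(y.sum())
    n_neg = len(y) - n_pos
    pts = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += (j - i) - int(y[i:j].sum())
        pts.append((fp / n_neg, tp / n_pos))
        i = j
    return np.array(pts)


def _logauc_segment(f1: float, t1: float, f2: float, t2: float,
                    floor: float) -> float:
    """∫ TPR d(log10 FPR) over the ROC segment clipped to [floor, 1];
    TPR is linear in FPR on the segment."""
    lo, hi = max(f1, floor), min(f2, 1.0)
    if hi <= lo:
        return 0.0
    if f2 == f1:
        return 0.0
    slope = (t2 - t1) / (f2 - f1)
    a = t1 + slope * (lo - f1)  # TPR at lo
    # ∫ (a + slope (f - lo)) dlog10 f = (a - slope*lo) ln(hi/lo)/ln10 + slope (hi-lo)/ln10
    ln10 = math.log(10.0)
    return ((a - slope * lo) * math.log(hi / lo) + slope * (hi - lo)) / ln10


def enrichment_metrics(
    labelled_scores: Sequence[tuple[float, bool]],
    log_floor: float = 1e-3,
) -> EnrichmentResult:
    """ROC AUC and adjusted logAUC of a labelled docking-score list.

    Scores are energies (lower is better); ties are averaged.  The
    adjusted logAUC is the semilog ROC area over FPR in
    ``[log_floor, 1]`` normalized by ``|log10 log_floor|``, minus the same
    area for the random diagonal — so random scoring gives 0 and perfect
    early enrichment approaches ``1 - (1 - log_floor)/ln(10)/|log10
    log_floor|`` (0.8554 at the 1e-3 floor).
    """
    scores = np.array([s for s, _ in labelled_scores], dtype=float)
    labels = np.array([l for _, l in labelled_scores], dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one ligand and one decoy")
    pts = _roc_points(scores, labels)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))

    norm = abs(math.log10(log_floor))
    area = 0.0
    rand_area = 0.0
    for k in range(1, len(pts)):
        f1, t1 = pts[k - 1]
        f2, t2 = pts[k]
        area += _logauc_segment(f1, t1, f2, t2, log_floor)
        rand_area += _logauc_segment(f1, f1, f2, f2, log_floor)
    adjusted = (area - rand_area) / norm
    return EnrichmentResult(
        roc_points=pts,
        auc=auc,
        adjusted_logauc=adjusted,
        n_ligands=n_pos,
        n_decoys=n_neg,
    )


def auc_mann_whitney(labelled_scores: Sequence[tuple[float, bool]]) -> float:
    """U-statistic AUC (pairwise-comparison count with half-credit ties);
    equals the trapezoid ROC AUC — kept as an independent cross-check."""
    pos = [s for s, l in labelled_scores if l]
    neg = [s for s, l in labelled_scores if not l]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p < q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


# ---------------------------------------------------------------------------
# Charge-composition check
# ---------------------------------------------------------------------------

@dataclass
class ChargeEnrichment:
    top_fraction: float
    per_class_top: dict[str, float]
    per_class_overall: dict[str, float]
    monoanion_enriched: bool

    def summary(self) -> str:
        lines = [
            f"Charge composition of top {self.top_fraction:.0%}",
            "=" * 36,
            f"{'class':<8}{'top':>8}{'overall':>10}",
        ]
        for cls in sorted(self.per_class_overall):
            lines.append(
                f"{cls:<8}{self.per_class_top.get(cls, 0.0):>8.3f}"
                f"{self.per_class_overall[cls]:>10.3f}"
            )
        lines.append(f"monoanions enriched: {self.monoanion_enriched}")
        return "\n".join(lines)


def charge_enrichment_check(
    results: Sequence[tuple[float, str]],
    top_fraction: float = 0.1,
) -> ChargeEnrichment:
    """Compare the charge-class composition of the best-scored fraction
    against the whole set; passes when monoanions ("-1") occupy at least
    their overall share of the top ranks."""
    if not 0 < top_fraction <= 1:
        raise ValueError("top_fraction must be in (0, 1]")
    scores = np.array([s for s, _ in results], dtype=float)
    classes = [c for _, c in results]
    n = len(results)
    n_top = max(1, int(round(top_fraction * n)))
    order = np.argsort(scores, kind="stable")
    top_classes = [classes[i] for i in order[:n_top]]

    def frac(seq: Sequence[str]) -> dict[str, float]:
        out: dict[str, float] = {}
        for c in seq:
            out[c] = out.get(c, 0.0) + 1.0
        return {k: v / len(seq) for k, v in out.items()}

    overall = frac(classes)
    top = frac(top_classes)
    mono_top = top.get("-1", 0.0)
    mono_all = overall.get("-1", 0.0)
    return ChargeEnrichment(
        top_fraction=top_fraction,
        per_class_top=top,
        per_class_overall=overall,
        monoanion_enriched=mono_top >= mono_all and mono_all > 0,
    )
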