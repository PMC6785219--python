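"""Stringent annotation-based evaluation, F-scores, PR curves, grid tuning.

A prediction counts as a true positive only under three simultaneous rules:
same strand as the annotated precursor, overlap of at least 50% of the
annotation's length, and the correct fold direction (each annotated mature
must fall on the same arm of the predicted fold as the annotation says).
Same-strand calls failing either of the latter two are "overlap" false
positives; opposite-strand overlaps are antisense false positives; the rest
are novel calls.

Two F statistics are reported side by side: the harmonic mean
f1 = 2PR/(P+R), and the tabulated variant f_paper = PR/(P+R) = f1/2 that
reproduces the published comparison table's printed column.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

TP = "TP"
FP_OVERLAP = "FP_overlap"
FP_ANTISENSE = "FP_antisense"
FP_NOVEL = "FP_novel"
FN = "FN"

#: pseudocount (ARPM) for knockdown log fold changes
LFC_PSEUDOCOUNT = 0.015


def _overlap(a_start, a_end, b_start, b_end) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start))


def _predicted_arm(pred, position: int) -> str | None:
    """Arm of a genomic position within the prediction's fold (via the main
    loop), or None when the fold has no loop to orient by."""
    if pred.loop_span is None:
        return None
    if pred.strand == "+":
        local = position - pred.start
    else:
        local = pred.end - 1 - position
    loop_mid = (pred.loop_span[0] + pred.loop_span[1]) / 2
    return "5p" if local < loop_mid else "3p"


def classify_prediction(pred, annotations) -> str:
    """Label one prediction against the annotation set (TP / FP_overlap /
    FP_antisense / FP_novel)."""
    precursors = [a for a in annotations if a.kind == "precursor"]
    matures = [a for a in annotations if a.kind == "mature"]
    best_sense, best_sense_ov = None, 0
    antisense_hit = False
    for ann in precursors:
        if ann.chrom != pred.chrom:
            continue
        ov = _overlap(pred.start, pred.end, ann.start, ann.end)
        if not ov:
            continue
        if ann.strand != pred.strand:
            antisense_hit = True
        elif ov > best_sense_ov:
            best_sense, best_sense_ov = ann, ov
    if best_sense is None:
        return FP_ANTISENSE if antisense_hit else FP_NOVEL
    if best_sense_ov < 0.5 * len(best_sense):
        return FP_OVERLAP
    # fold direction: every annotated mature of this precursor with a known
    # arm must land on the same arm in the predicted fold
    for m in matures:
        if m.parent != best_sense.name or m.arm not in ("5p", "3p"):
            continue
        mid = (m.start + m.end) // 2
        arm = _predicted_arm(pred, mid)
        if arm is not None and arm != m.arm:
            return FP_OVERLAP
    return TP


def precision_recall(preds, annotations, expressed_names=None):
    """(precision, recall) under the stringent rules.

    ``expressed_names``: names of annotated precursors with at least one
    aligned read; when given, the recall denominator is restricted to them
    (unexpressed annotations cannot be recalled).  Returns None components
    when a denominator is zero.
    """
    labels = [classify_prediction(p, annotations) for p in preds]
    precursors = [a for a in annotations if a.kind == "precursor"]
    if expressed_names is not None:
        precursors = [a for a in precursors if a.name in expressed_names]
    n_tp_pred = sum(1 for lb in labels if lb == TP)
    # recall counts annotations recovered, not predictions (two predictions
    # hitting one annotation recall it once)
    recovered = set()
    for p, lb in zip(preds, labels):
        if lb != TP:
            continue
        for ann in precursors:
            if (
                ann.chrom == p.chrom
                and ann.strand == p.strand
                and _overlap(p.start, p.end, ann.start, ann.end)
                >= 0.5 * len(ann)
            ):
                recovered.add(ann.name)
    precision = n_tp_pred / len(labels) if labels else None
    recall = len(recovered) / len(precursors) if precursors else None
    return precision, recall


def f_scores(p: float, r: float) -> tuple[float, float]:
    """(f1, f_paper): the harmonic mean 2PR/(P+R) and the tabulated variant
    PR/(P+R).  Both 0 when P = R = 0 by convention."""
    if p == 0 and r == 0:
        return 0.0, 0.0
    f1 = 2 * p * r / (p + r)
    return f1, f1 / 2


def pr_curve_auprc(scores, labels):
    """Precision/recall at every score threshold, plus trapezoidal AUPRC.

    ``labels`` are binary ground truth per scored locus.  Thresholds sweep
    the distinct scores from high to low; the area is the trapezoid over
    recall with the curve anchored at recall 0 with the highest-threshold
    precision.  Raises on a single-class input (the curve is undefined).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("PR curve undefined: only one class present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    lb = labels[order]
    tp = np.cumsum(lb)
    fp = np.cumsum(1 - lb)
    # evaluate at each distinct threshold (last index of every tie block)
    last = np.nonzero(np.r_[s[1:] != s[:-1], True])[0]
    precision = tp[last] / (tp[last] + fp[last])
    recall = tp[last] / n_pos
    r_pts = np.r_[0.0, recall]
    p_pts = np.r_[precision[0], precision]
    auprc = float(np.trapezoid(p_pts, r_pts))
    return list(zip(recall.tolist(), precision.tolist())), auprc


@dataclass
class TuningResult:
    y_hprf: float
    e_th: float
    x: int
    f_score: float
    objective: str
    grid: list  # full table of evaluated points


def tune_grid(
    train_fn,
    eval_fn,
    y_grid,
    e_grid,
    x_grid,
    objective: str = "f1",
) -> TuningResult:
    """Exhaustive grid search over (y_HPRF, E_th, X) maximizing F-score.

    ``train_fn(x)`` fits models at negative-sampling ratio 1:x and returns an
    opaque context; ``eval_fn(context, y, e)`` evaluates thresholds on the
    tuning sample and returns (precision, recall).  Ties break toward the
    smaller X, then the larger y (more conservative), then the larger E.
    """
    if not (list(y_grid) and list(e_grid) and list(x_grid)):
        raise ValueError("empty tuning grid")
    obj_idx = {"f1": 0, "f_paper": 1}[objective]
    rows = []
    best = None
    for x in x_grid:
        ctx = train_fn(x)
        for y in y_grid:
            for e in e_grid:
                p, r = eval_fn(ctx, y, e)
                f = f_scores(p or 0.0, r or 0.0)[obj_idx]
                rows.append({"x": x, "y": y, "e": e, "P": p, "R": r, "f": f})
                key = (f, -x, y, e)
                if best is None or key > best[0]:
                    best = (key, x, y, e, f)
    _, x, y, e, f = best
    return TuningResult(y_hprf=y, e_th=e, x=x, f_score=f,
                        objective=objective, grid=rows)


def dicer_log_fold_change(
    kd_arpm: float, wt_arpm: float, pseudocount: float = LFC_PSEUDOCOUNT
) -> float:
    """log2((kd + c) / (wt + c)) with the ARPM pseudocount c."""
    return math.log2((kd_arpm + pseudocount) / (wt_arpm + pseudocount))
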