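"""Contact-prediction scoring: accuracy/coverage, aggregation, top-n protocol.

Accuracy (specificity) is the fraction of predicted contacts that are
observed, TP/(TP+FP); coverage (sensitivity) is the fraction of observed
contacts that were predicted, TP/(TP+FN). Both are percentages. Scores are
computed per protein and macro-averaged over the set; dispersion is
reported both as the sample standard deviation and the standard error of
the mean. Only pairs passing the separation mask used at prediction time
enter the counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


class EvaluationError(ValueError):
    pass


PairSet = set[tuple[int, int]]


def _canon(pairs) -> PairSet:
    return {(min(i, j), max(i, j)) for i, j in pairs}


def accuracy(predicted, observed) -> float:
    """100 * |predicted ∩ observed| / |predicted| — TP/(TP+FP)."""
    predicted, observed = _canon(predicted), _canon(observed)
    if not predicted:
        raise EvaluationError("undefined accuracy: empty predicted set")
    return 100.0 * len(predicted & observed) / len(predicted)


def coverage(predicted, observed) -> float:
    """100 * |predicted ∩ observed| / |observed| — TP/(TP+FN)."""
    predicted, observed = _canon(predicted), _canon(observed)
    if not observed:
        raise EvaluationError("undefined coverage: empty observed set")
    return 100.0 * len(predicted & observed) / len(observed)


@dataclass
class ProteinScore:
    """Counts and scores for one protein (accuracy/coverage may be None
    when undefined, e.g. nothing was predicted)."""

    name: str
    n_correct: int
    n_predicted: int
    n_observed: int

    @property
    def accuracy(self) -> float | None:
        if self.n_predicted == 0:
            return None
        return 100.0 * self.n_correct / self.n_predicted

    @property
    def coverage(self) -> float | None:
        if self.n_observed == 0:
            return None
        return 100.0 * self.n_correct / self.n_observed


def score_protein(name: str, predicted, observed) -> ProteinScore:
    predicted, observed = _canon(predicted), _canon(observed)
    return ProteinScore(
        name=name,
        n_correct=len(predicted & observed),
        n_predicted=len(predicted),
        n_observed=len(observed),
    )


@dataclass
class ScoreReport:
    """Set-level macro means with dispersion, plus the per-protein rows."""

    per_protein: list[ProteinScore]
    mean_accuracy: float
    mean_coverage: float
    sd_accuracy: float
    sd_coverage: float
    se_accuracy: float
    se_coverage: float
    n_scored_accuracy: int
    n_scored_coverage: int
    n_excluded: int

    def to_dict(self) -> dict:
        return {
            "mean_accuracy": self.mean_accuracy,
            "mean_coverage": self.mean_coverage,
            "sd_accuracy": self.sd_accuracy,
            "sd_coverage": self.sd_coverage,
            "se_accuracy": self.se_accuracy,
            "se_coverage": self.se_coverage,
            "n_scored_accuracy": self.n_scored_accuracy,
            "n_scored_coverage": self.n_scored_coverage,
            "n_excluded": self.n_excluded,
            "per_protein": [
                {
                    "name": p.name,
                    "n_correct": p.n_correct,
                    "n_predicted": p.n_predicted,
                    "n_observed": p.n_observed,
                    "accuracy": p.accuracy,
                    "coverage": p.coverage,
                }
                for p in self.per_protein
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def to_tsv(self) -> str:
        lines = ["name\tn_correct\tn_predicted\tn_observed\taccuracy\tcoverage"]
        for p in self.per_protein:
            acc = "" if p.accuracy is None else f"{p.accuracy:.2f}"
            cov = "" if p.coverage is None else f"{p.coverage:.2f}"
            lines.append(
                f"{p.name}\t{p.n_correct}\t{p.n_predicted}\t{p.n_observed}\t{acc}\t{cov}"
            )
        lines.append(
            f"#mean\t\t\t\t{self.mean_accuracy:.2f}\t{self.mean_coverage:.2f}"
        )
        return "\n".join(lines) + "\n"


def _mean_sd_se(values: list[float]) -> tuple[float, float, float]:
    arr = np.asarray(values, dtype=float)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
    return mean, sd, sd / np.sqrt(len(arr)) if len(arr) else 0.0


def aggregate(per_protein: list[ProteinScore]) -> ScoreReport:
    """Unweighted (macro) means over proteins; undefined scores are
    excluded from the means (not counted as zero) and the exclusion
    count is reported."""
    if not per_protein:
        raise EvaluationError("nothing to aggregate")
    accs = [p.accuracy for p in per_protein if p.accuracy is not None]
    covs = [p.coverage for p in per_protein if p.coverage is not None]
    if not accs and not covs:
        raise EvaluationError("nothing to aggregate: all scores undefined")
    mean_a, sd_a, se_a = _mean_sd_se(accs) if accs else (float("nan"),) * 3
    mean_c, sd_c, se_c = _mean_sd_se(covs) if covs else (float("nan"),) * 3
    return ScoreReport(
        per_protein=list(per_protein),
        mean_accuracy=mean_a, mean_coverage=mean_c,
        sd_accuracy=sd_a, sd_coverage=sd_c,
        se_accuracy=se_a, se_coverage=se_c,
        n_scored_accuracy=len(accs), n_scored_coverage=len(covs),
        n_excluded=len(per_protein) - min(len(accs), len(covs)),
    )


def top_n_select(prediction_map, n: int) -> list[tuple[int, int]]:
    """The n highest-probability masked pairs of a prediction map.

    Ties break toward smaller i, then smaller j; if fewer than n pairs are
    available, all are returned.
    """
    if n < 1:
        raise EvaluationError("n must be >= 1")
    items = sorted(
        zip(prediction_map.pairs, prediction_map.probabilities),
        key=lambda t: (-t[1], t[0][0], t[0][1]),
    )
    return [pair for pair, _p in items[:n]]


def compare_protocol(
    maps: dict[str, "object"],
    truths: dict[str, PairSet],
    per_protein: bool = False,
) -> dict:
    """Top-n comparison at n in {floor(T/2), floor(2T/3), T}.

    T is the total number of observed contacts. By default the protocol is
    pooled: predictions of all proteins are ranked together and the n
    highest-probability pairs selected across the whole set; with
    ``per_protein`` each protein contributes its own T and top-n. The
    final indices are the means over the three n settings.
    """
    names = sorted(maps)
    if set(names) - set(truths):
        raise EvaluationError("truth missing for some proteins")
    truths = {k: _canon(v) for k, v in truths.items()}
    t_total = sum(len(truths[nm]) for nm in names)
    if t_total == 0:
        raise EvaluationError("no observed contacts")

    results = {"n_values": [t_total // 2, (2 * t_total) // 3, t_total],
               "per_n": [], "per_protein_mode": per_protein}
    fractions = (lambda t: t // 2, lambda t: (2 * t) // 3, lambda t: t)
    accs, covs = [], []
    for frac, n_sel in zip(fractions, results["n_values"]):
        if per_protein:
            scores = []
            for nm in names:
                t_i = len(truths[nm])
                if t_i == 0:
                    continue
                sel = set(top_n_select(maps[nm], max(1, frac(t_i))))
                scores.append(score_protein(nm, sel, truths[nm]))
            rep = aggregate(scores)
            acc, cov = rep.mean_accuracy, rep.mean_coverage
        else:
            pooled = []
            for nm in names:
                pm = maps[nm]
                pooled.extend(
                    (p, nm, pair) for pair, p in zip(pm.pairs, pm.probabilities)
                )
            pooled.sort(key=lambda t: (-t[0], t[1], t[2][0], t[2][1]))
            sel = pooled[: max(1, n_sel)]
            tp = sum(1 for _p, nm, pair in sel if pair in truths[nm])
            acc = 100.0 * tp / len(sel)
            cov = 100.0 * tp / t_total
        results["per_n"].append({"n": n_sel, "accuracy": acc, "coverage": cov})
        accs.append(acc)
        covs.append(cov)
    results["mean_accuracy"] = float(np.mean(accs))
    results["mean_coverage"] = float(np.mean(covs))
    return results
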