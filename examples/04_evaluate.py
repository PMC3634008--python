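"""Score contact predictions: accuracy, coverage and the top-n protocol.

Accuracy (specificity) = TP/(TP+FP); coverage (sensitivity) = TP/(TP+FN),
both macro-averaged over proteins with SD and SE reported. The top-n
protocol compares methods at n = T/2, 2T/3 and T highest-probability
pairs, where T is the total number of true contacts.
"""

import numpy as np

from contactcascade import aggregate, compare_protocol, score_protein
from contactcascade.cascade_model import PredictionMap

truth_a = {(1, 9), (2, 10), (3, 12), (5, 14)}
truth_b = {(1, 8), (4, 12), (6, 15)}

pred_a = {(1, 9), (2, 10), (3, 12), (7, 16), (8, 17)}  # 3 of 5 correct
pred_b = {(1, 8), (4, 12)}                             # 2 of 2 correct

scores = [score_protein("protA", pred_a, truth_a),
          score_protein("protB", pred_b, truth_b)]
report = aggregate(scores)
for p in report.per_protein:
    print(f"{p.name}: accuracy {p.accuracy:.1f}%  coverage {p.coverage:.1f}%")
print(f"macro mean: accuracy {report.mean_accuracy:.2f}% "
      f"(SD {report.sd_accuracy:.2f}, SE {report.se_accuracy:.2f}), "
      f"coverage {report.mean_coverage:.2f}%")

maps = {}
for name, pred, truth in (("protA", pred_a, truth_a), ("protB", pred_b, truth_b)):
    pairs = sorted(pred | truth)
    probs = np.array([0.9 if p in pred else 0.1 for p in pairs])
    maps[name] = PredictionMap(length=20, pairs=pairs, probabilities=probs,
                               threshold=0.5, name=name)
comparison = compare_protocol(maps, {"protA": truth_a, "protB": truth_b})
print(f"top-n protocol: n = {comparison['n_values']} "
      f"(T = {comparison['n_values'][-1]} true contacts pooled)")
print(f"mean accuracy {comparison['mean_accuracy']:.2f}%  "
      f"mean coverage {comparison['mean_coverage']:.2f}%")
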