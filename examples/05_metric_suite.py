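"""The evaluation metric suite on a worked confusion matrix.

Uses the binary table TP=40, FN=10, TN=45, FP=5 (100 records) and shows
every statistic the study reports, including the two G-mean variants and
the literal sensitivity/specificity ratio printed as "AUC" in the study's
formula list (the headline AUC here is the conventional ROC area).
"""

import numpy as np

from tokenmixer import ConfusionMatrix, binary_report
from tokenmixer.metrics import gmean, kappa, mcc, rate_metrics, roc_auc

cm = ConfusionMatrix.from_binary(tp=40, tn=45, fp=5, fn=10)
v = rate_metrics(cm).values
print("accuracy     ", round(v["accuracy"], 4))      # 0.85
print("sensitivity  ", round(v["sensitivity"], 4))   # 0.80
print("precision    ", round(v["precision"], 4))     # 0.8889
print("specificity  ", round(v["specificity"], 4))   # 0.90
print("F1           ", round(v["f1"], 4))            # 0.8421
print("MCC          ", round(mcc(cm), 4))            # 0.7035
stats = kappa(cm)
print(f"kappa         {stats.kappa:.4f}  (Po={stats.po}, Pe={stats.pe})")
g_paper, g_conv = gmean(v["precision"], v["sensitivity"],
                        v["sensitivity"], v["specificity"])
print(f"G (printed)   {g_paper:.4f}   G (conventional) {g_conv:.4f}")

# ROC from continuous scores: trapezoidal area = Mann-Whitney statistic
y = np.array([0, 0, 1, 1])
scores = np.array([0.1, 0.4, 0.35, 0.8])
pts, auc = roc_auc(y, scores)
print("ROC points (fpr, tpr):", [(p[0], p[1]) for p in pts])
print("AUC:", auc)  # 0.75: of the 4 positive-negative pairs, 3 are ordered
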