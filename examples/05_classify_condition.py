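"""Predict session condition from per-burst features.

Builds a small cohort (4 subjects x saline/EtOH-like conditions) with the
default condition effects (burst rate x1.5, CA1 duration x0.7 under
"etoh"), extracts waveform/spectral/contextual features per burst, and
evaluates an XGBoost classifier with leave-subjects-out cross-validation.
"""

import numpy as np
import pandas as pd

from thetaburst import SessionParams, build_table, generate_cohort, train_eval
from thetaburst.bursts import extract_features

base = dict(duration_s=600.0, regions=("MS", "CA1"), coupling_probability=0.7)
cohort = generate_cohort(
    4,
    {
        "saline": SessionParams(**base, condition="saline"),
        "etoh": SessionParams(**base, condition="etoh"),
    },
    seed=42,
    with_tracking=False,
)

events_by_session = {}
for rec, _, truth in cohort:
    rows, prev = [], None
    for ev in sorted(truth.true_bursts["CA1"], key=lambda e: e.start_s):
        rows.append(dict(extract_features(ev, rec.signals["CA1"], rec.fs, prev_event=prev)))
        prev = ev
    df = pd.DataFrame(rows)
    df["subject_id"] = rec.subject_id
    df["condition"] = truth.condition
    events_by_session[f"{rec.subject_id}_{truth.condition}"] = df

table = build_table(events_by_session)
print(f"{len(table.data)} bursts, {len(table.feature_cols)} features")
report = train_eval(table, folds=4, grouped=True, seed=0)
print(f"grouped-CV ROC AUC = {report.roc_auc:.3f}, average precision = {report.average_precision:.3f}")
print(f"accuracy at 0.5 threshold = {report.accuracy:.3f}")
print("top features:", ", ".join(report.feature_importances.head(3).index))

# AUC well above 0.5 on held-out subjects means burst morphology alone
# carries the condition signature; burst duration should rank first because
# the injected effect shortens CA1 bursts.
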