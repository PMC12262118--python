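"""Decode exposure day from single-trial differential responses.

Trains a shrinkage-LDA classifier independently at each epoch timepoint on
the three frontal channels of the deviant-minus-standard single trials, with
stratified 5-fold cross-validation repeated to stabilise the estimate, and
tests window-mean AUCs against chance with a one-tailed sign-flip
permutation test.
"""

import numpy as np

import erplearn as el

cfg = el.StudyConfig(
    n_participants=4, n_days=2,
    sequence=el.SequenceSpec(n_total=600, seed=5),
    seed=23,
)

pairs_by = {}
for sess in el.simulate_study(cfg):
    pairs_by[(sess.participant, sess.day)] = el.preprocess_session(
        sess.recording, sess.events,
        participant=sess.participant, day=sess.day)

win = el.AnalysisWindow("MMN", 189.0, 259.0, 224.0)
participant_aucs = []
for p in sorted({k[0] for k in pairs_by}):
    feats = el.make_features({1: pairs_by[(p, 1)], 2: pairs_by[(p, 2)]},
                             deviant_type="dev_large")
    curve = el.temporal_decoding(feats, folds=5, repeats=25, seed=1)
    auc = el.window_mean_auc(curve, win)
    participant_aucs.append(auc)
    print(f"{p}: day-1 vs day-2 decoding, MMN-window mean AUC = {auc:.3f}")

stat = el.group_permutation_ttest(np.array(participant_aucs),
                                  n_perm=10_000, m_comparisons=1, seed=2)
print(f"\ngroup mean AUC {stat.mean_auc:.3f}, t = {stat.t:.2f}, "
      f"one-tailed permutation p = {stat.p:.4f}")
# AUC 0.5 is chance; the generator programs a small day-2 amplitude offset,
# so with enough trials the window AUC sits modestly above chance.  The
# permutation p is exact here (2^4 sign patterns enumerated), so its floor
# is 1/16 with four participants.
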