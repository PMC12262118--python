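"""Simulate two short sessions, preprocess them, and derive the MMN/P3a
analysis windows from the grand-average differential waveform.

The windows are data-driven: the MMN peak is the most negative post-stimulus
point of the grand average (pooled over participants, days and deviant
types), the P3a peak the most positive, and each window extends +/-35 ms
around its peak.
"""

import erplearn as el

cfg = el.StudyConfig(
    n_participants=2, n_days=1,
    sequence=el.SequenceSpec(n_total=600, seed=3),
    seed=17,
)

all_pairs = []
for sess in el.simulate_study(cfg):
    pairs = el.preprocess_session(sess.recording, sess.events,
                                  participant=sess.participant, day=sess.day)
    print(f"{sess.participant} day {sess.day}: {pairs.n_pairs} balanced "
          f"deviant/standard pairs after rejection")
    all_pairs.append(pairs)

diffs = [el.average_differential(p.select_type(t))
         for p in all_pairs for t in ("dev_small", "dev_large")]
grand = el.grand_average(diffs)
mmn, p3a = el.select_windows(grand)

print(f"\nMMN window: {mmn.start_ms:.0f}-{mmn.end_ms:.0f} ms "
      f"(peak {mmn.peak_ms:.0f} ms)")
print(f"P3a window: {p3a.start_ms:.0f}-{p3a.end_ms:.0f} ms "
      f"(peak {p3a.peak_ms:.0f} ms)")

for m in el.measure_components(all_pairs, (mmn, p3a)):
    print(f"{m.participant} day {m.day} {m.deviant_type:9s} {m.component}: "
          f"{m.amplitude_uv:+.2f} uV at {m.latency_ms:.0f} ms "
          f"({m.n_trials} trials)")
# Amplitudes are mean voltages of the deviant-minus-standard trace over the
# window (negative for MMN, positive for P3a); latency is the window's
# extreme sample.  With only ~60 deviants per type these single-session
# estimates are noisy; the multi-day stages average many more trials.
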