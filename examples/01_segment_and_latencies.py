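"""Build turns from a tiny utterance table and compute response latencies.

A four-utterance parent-child exchange with one backchannel shows the two
segmentation rules: consecutive same-speaker utterances consolidate into a
turn, and a backchannel folds into the speaker's next substantial turn
without advancing its onset.
"""

from turntaking import Utterance, compute_latencies, merge_backchannels

session = dict(dyad_id="d1", child_id="c1", group="typical", visit=1,
               context="convo_parent")
utterances = [
    Utterance(speaker_role="adult", onset_s=0.0, offset_s=3.0, **session),
    Utterance(speaker_role="child", onset_s=1.0, offset_s=1.3,
              is_backchannel=True, **session),           # "mm-hm"
    Utterance(speaker_role="child", onset_s=3.4, offset_s=6.0, **session),
    Utterance(speaker_role="adult", onset_s=5.8, offset_s=7.5, **session),
]

turns = merge_backchannels(utterances)
print("turns:")
for t in turns:
    print(f"  {t.speaker_role:5s} [{t.onset_s:.1f}, {t.offset_s:.1f}]"
          f"  merged_backchannel={t.merged_backchannel}")

obs = compute_latencies(turns, session)
print("latencies:")
for o in obs:
    kind = "overlap" if o.is_overlap else "gap"
    print(f"  turn {o.turn_index} ({o.speaker_role}): {o.latency_s*1000:+.0f} ms ({kind})")

# The child's 400 ms latency runs from the adult's offset (3.0 s) to the
# substantial utterance onset (3.4 s) - the backchannel never counts as a
# turn start. The adult's -200 ms latency is an overlap: they started
# speaking 200 ms before the child finished.
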