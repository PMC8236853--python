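"""Generate a small synthetic cohort and look at its structure.

The generator emulates picture-description speech of AD and non-AD
participants: token sequences with pauses and timings, per-token acoustic
descriptor tables, a word-embedding lexicon and labels.  Class effects
(acoustic mean shift, lexical preferences, late noun positions for AD) are
injected additively.
"""

from adr_speech import SyntheticConfig, encode_pause_tokens, generate_cohort

config = SyntheticConfig(n_train_per_class=4, n_test_per_class=2, seed=1)
cohort = generate_cohort(config)

print(f"cohort: {len(cohort.train)} train / {len(cohort.test)} test participants")
record = cohort.train[0]
n_pauses = sum(t.is_pause for t in record.tokens)
print(f"\nparticipant {record.participant_id} ({record.label}):")
print(f"  {len(record.tokens)} tokens = {len(record.transcript)} words + {n_pauses} pauses")
print(f"  first 12 words: {' '.join(record.transcript[:12])}")
print(f"  with encoded pauses: {' '.join(encode_pause_tokens(record.tokens)[:15])}")
print(f"  acoustic table: {cohort.acoustic[record.participant_id].shape} "
      "(one row per token, one column per descriptor)")
print(f"  lexicon: {len(cohort.lexicon)} words, dimension {cohort.lexicon.dim}")

# The pause symbols encode pause length: ',' short (0.05-0.5 s),
# '.' medium (0.5-2 s), '...' long (> 2 s); sub-50 ms pauses are dropped.
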