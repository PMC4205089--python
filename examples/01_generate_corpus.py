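"""Generate the default synthetic registry corpus and inspect it.

Builds the four-domain corpus (437 trials) with planted status conflicts,
format variants and barrier criteria, and prints a flat summary.  The same
corpus can be written to disk as one classic-dialect XML file per trial plus
a manifest CSV.
"""

from ctgaudit import corpus_to_frame
from ctgaudit.synthetic_data import default_corpus_spec, generate_corpus

corpus, truth = generate_corpus(default_corpus_spec(seed=1))

frame = corpus_to_frame(corpus)
print(frame.groupby("domain_tag").size().rename("trials"))
print()
print(frame.head(3).to_string())
print()
some = corpus.records[0]
print(f"--- eligibility text of {some.nct_id} "
      f"(planted format: {truth.trials[some.nct_id].format_label}) ---")
print(some.eligibility_text)
# Per-domain trial counts mirror a realistic four-domain registry snapshot;
# each record carries the dates, status, locations and contacts the audits use.
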