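"""Corpus filtering: inclusion/exclusion rules with per-rule bookkeeping.

Builds the eight-record fixture (one violator per exclusion rule plus one clean
post), runs the filter stage, and prints the report. Each removal is attributed
to the first failing rule in the fixed order date, language, keyword, length,
retweet/quote, bot, non-medical-use — so the counts partition the removed set.
"""

from nmutext import apply_filters, generate_filter_fixture

synth, config = generate_filter_fixture(seed=0)
kept, report = apply_filters(synth.tweets, config)

print(f"records in:  {report.n_in}")
print(f"records out: {report.n_out}  (the clean record: {kept[0].tweet_id!r})")
print("removed, by first failing rule:")
for rule, count in sorted(report.counts_removed.items()):
    print(f"  {rule:<14} {count}")

# n_in = n_out + total removals: the attribution is a partition
assert report.n_in == report.n_out + sum(report.counts_removed.values())
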