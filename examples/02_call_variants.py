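"""Pileup parsing and per-sample variant calling with editing thresholds.

Variant criteria: base quality >= 25, quality-filtered depth >= 10,
alternative allele depth >= 2, allele frequency >= 1%. A false-positive
screen then drops calls whose alternative reads all sit on one strand or
show depressed base quality.
"""

from editscan import (
    CallThresholds,
    call_variants,
    false_positive_filter,
    parse_pileup_line,
    summarize_site,
)

# a 6-column mpileup record: 20 reference matches (10 per strand) and
# 5 A's on the forward strand, all at Phred 30 ('?')
line = "chr1\t1042\tG\t25\t" + "." * 10 + "," * 10 + "AAAAA" + "\t" + "?" * 25
site = parse_pileup_line(line)
summary = summarize_site(site, q_min=25)
calls = call_variants(summary, CallThresholds(), sample_id="demo")

for call in calls:
    ok, reason = false_positive_filter(call)
    print(f"{call.contig}:{call.pos} {call.ref_allele}>{call.alt_allele} "
          f"depth={call.total_depth} alt={call.alt_depth} aaf={call.aaf:.3f} "
          f"fpfilter={'pass' if ok else reason}")

# The call's allele frequency (5/25 = 0.20) is the site's editing level in
# this sample; it fails the strand-bias screen because all five alternative
# reads are forward-strand while reference reads occur on both strands.
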