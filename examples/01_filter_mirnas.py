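"""Quality-filter mature miRNAs by read support, length and orientation.

Builds a small table around the abundance boundary (the "more than 1400
reads" criterion is strict) and the inclusive 19-25 nt length window, then
prints who survived and why the rest were rejected.
"""

from xkmir import MatureMiRNA, filter_mirnas

mirnas = [
    MatureMiRNA("zma-miR529-5p", "zma", "AGAAGAGAGAGAGUACAGCCU", read_count=5000),
    MatureMiRNA("demo-at-boundary", "zma", "AGAAGAGAGAGAGUACAGCCA", read_count=1400),
    MatureMiRNA("demo-just-above", "zma", "AGAAGAGAGAGAGUACAGG", read_count=1401),
    MatureMiRNA("demo-too-long", "zma", "ACGUACGUACGUACGUACGUACGUAC", read_count=9000),
]

report = filter_mirnas(mirnas)
print(f"kept {len(report.kept)} of {report.n_input}:")
for m in report.kept:
    print(f"  {m.mirna_id}  len={len(m)}  reads={m.read_count}")
print("rejected:")
for m, reasons in report.rejected:
    print(f"  {m.mirna_id}  {','.join(sorted(reasons))}")

# A count of exactly 1400 fails (strict bound); lengths 19 and 25 pass
# (inclusive window).  Only records passing all three criteria continue
# into the target search.
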