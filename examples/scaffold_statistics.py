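"""Assembly-level GC and scaffold-length statistics.

Builds an assembly of 200 small scaffolds (80 kb each, 16.0 Mb) plus 30
large ones (160 kb each, 4.8 Mb) — the length profile of a fragmented
parasite assembly — and partitions it at the standard 100-kb cutoff.
Analyses of fragmented assemblies are usually restricted to the scaffolds
at or above that cutoff.
"""

from gcmosaic import GenomeAssembly, SequenceRecord, scaffold_stats

records = [
    SequenceRecord(id=f"small{i}", description="", sequence="ATTA" * 20_000)
    for i in range(200)
] + [
    SequenceRecord(id=f"large{i}", description="", sequence="ATGC" * 40_000)
    for i in range(30)
]
stats = scaffold_stats(GenomeAssembly(records=records), cutoff=100_000)

print(f"records:            {stats.n_records}")
print(f"overall GC:         {stats.gc_percent:.1f} %")
print(f"total length:       {stats.total_mb:.1f} Mb")
print(f"< 100 kb:           {stats.mb_below_cutoff:.1f} Mb ({stats.pct_below:.1f} %)")
print(f">= 100 kb:          {stats.mb_at_or_above_cutoff:.1f} Mb ({stats.pct_at_or_above:.1f} %)")
# Only 23.1% of this assembly is in scaffolds large enough for 25-kb window
# analysis; the percentages always sum to 100 before rounding.
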