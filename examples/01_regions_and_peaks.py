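"""Merge overlapping CNVs into CNVRs and find their coverage peak regions.

A handful of pathogenic deletion calls piled over one locus: the peak
region (the plateau of highest recurrent coverage) is the proxy for the
critical region most likely to contain the causative gene.
"""

from dosagescope import CnvRecord, coverage_profile, find_peak_regions, merge_cnvrs

calls = [
    CnvRecord("case1", "1", 10_000, 60_000, "loss", "pathogenic"),
    CnvRecord("case2", "1", 25_000, 80_000, "loss", "pathogenic"),
    CnvRecord("case3", "1", 30_000, 70_000, "loss", "pathogenic"),
    CnvRecord("case4", "1", 120_000, 150_000, "loss", "pathogenic"),
]

for region in merge_cnvrs(calls, scope="loss_only"):
    profile = coverage_profile(region)
    print(f"CNVR {region.region_id}: {region.chromosome}:{region.start}-{region.end} "
          f"({len(region.members)} CNVs)")
    print("  coverage:", " ".join(f"[{s}-{e})x{d}" for s, e, d in profile.segments))
    for peak in find_peak_regions(profile):
        print(f"  peak {peak.peak_id}: [{peak.start}-{peak.end}) depth {peak.depth}")

# The first CNVR's peak is the subinterval all three cases share — the
# recurrently deleted core. The solitary call keeps its whole extent as a
# depth-1 peak, so rare single-case CNVs are not discarded.
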