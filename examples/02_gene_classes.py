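"""Assign genes to dosage classes from their CNV overlap pattern.

Benign CNVs are used whole; pathogenic CNVs are represented by their peak
regions. A gene only in pathogenic peaks is Class P (candidate dosage
sensitive); one in both interpretations of the same CNV type is a Class X
passenger; a peak whose only Class P gene is unique is a solitary call —
the prime candidate for the region's pathogenicity.
"""

from dosagescope import GeneRecord, assign_classes, find_solitary

genes = [
    GeneRecord("TOLERANT1", "1", 1_000, 5_000),
    GeneRecord("CANDIDATE1", "1", 20_000, 28_000),
    GeneRecord("PASSENGER1", "1", 40_000, 46_000),
    GeneRecord("HAPLO1", "1", 60_000, 66_000),
]

benign_gain = [("1", 500, 6_000), ("1", 39_000, 47_000)]
benign_loss = []
path_gain_peaks = [("1", 41_000, 45_000)]
path_loss_peaks = [("1", 19_000, 30_000), ("1", 58_000, 70_000)]
# HAPLO1 additionally sits in a benign gain: tolerated extra copies but
# pathogenic loss is the classic haploinsufficiency pattern (BG/PL)
benign_gain.append(("1", 59_000, 67_000))

assignments = assign_classes(genes, benign_gain, benign_loss,
                             path_gain_peaks, path_loss_peaks)
for a in assignments:
    print(f"{a.gene_id:12s} -> {a.label.value:6s} membership={a.membership}")

calls = find_solitary(path_loss_peaks, assignments, genes)
for c in calls:
    print(f"peak {c.region_id}: class P genes {c.class_p_gene_ids or '-'} "
          f"solitary={c.solitary}")

# CANDIDATE1 is Class P and the only such gene in its peak: a solitary
# candidate causative gene. PASSENGER1 appears in benign and pathogenic
# gains alike, so it is an unlikely driver (Class X).
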