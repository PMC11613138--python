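"""NOESY volumes to distances and MD restraints.

Cross-peak volumes scale as d^-6; the cytosine H5-H6 pair (2.9 Å by
covalent geometry) calibrates the scale.  Distances are compared to
B-DNA expectations and exported as flat-well restraints for MD.
"""

from meltfold import noe, synth

geometry = [
    (("C-4", "H5"), ("C-4", "H6"), 2.9),
    (("C-5", "H5"), ("C-5", "H6"), 2.9),
    (("A6", "H8"), ("A6", "H1'"), 3.7),   # outer-segment intranucleotide
    (("G5", "H8"), ("A6", "H1'"), 3.2),   # outer-segment sequential
    (("T-2", "M7"), ("A-1", "H8"), 3.4),  # loop contact (methyl)
]
cfg = synth.SynthConfig(seed=3)  # 5% volume noise
peaks = synth.synth_noesy_peaks(geometry, scale=1e6, cfg=cfg)

distances = noe.peaks_to_distances(peaks)
print("pair                          d (A)   input")
truth = {tuple(sorted((a, b))): d for a, b, d in geometry}
for de in distances:
    key = tuple(sorted(de.pair))
    label = f"{de.pair[0][0]} {de.pair[0][1]} - {de.pair[1][0]} {de.pair[1][1]}"
    print(f"{label:28s}  {de.d:5.2f}   {truth[key]:.2f}")
print("\n5% volume noise maps to <1% distance error (sixth-root compression).\n")
print(noe.export_restraints(distances, fractional=0.2))
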