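"""Build the two built-in diagnostic hierarchies and derive auxiliary labels.

The CPSC2018 taxonomy merges 9 arrhythmia classes into 5 superclasses
(merge direction: the auxiliary task is the coarser level); the PTB-XL
taxonomy nests 23 subclasses under 5 superclasses (split direction: the
auxiliary task is the finer level).  A random regrouping with the same
group sizes serves as the control auxiliary task.
"""

from ecgmtl import cpsc_hierarchy, derive_aux_labels, ptbxl_hierarchy, \
    random_hierarchy

cpsc = cpsc_hierarchy()
print(f"CPSC2018: {len(cpsc.fine_classes)} classes -> "
      f"{len(cpsc.coarse_classes)} superclasses {cpsc.coarse_classes}")
print("  LBBB and RBBB merge into:", derive_aux_labels({"LBBB", "RBBB"}, cpsc))
print("  a record labelled {SNR, STD} gets aux labels:",
      derive_aux_labels({"SNR", "STD"}, cpsc))

ptbxl = ptbxl_hierarchy()
print(f"PTB-XL: {len(ptbxl.fine_classes)} subclasses under "
      f"{len(ptbxl.coarse_classes)} superclasses")
print("  children of MI:", ptbxl.children_of("MI"))

control = random_hierarchy(cpsc, seed=0)
print("random control grouping (same group sizes, no clinical meaning):")
for coarse in control.coarse_classes:
    print(f"  {coarse}: {control.children_of(coarse)}")
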