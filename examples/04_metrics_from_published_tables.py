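"""Reproduce published aggregate metrics from per-class table entries.

The package ships the published per-class benchmark tables for this
architecture on CPSC2018 and PTB-XL.  The macro F1 is the unweighted mean
of per-class F1s, and each F1 cell is the harmonic mean of its printed
precision/recall pair — both recomputable exactly.
"""

from ecgmtl import benchmarks, f1_score, macro_f1

cpsc_f1 = macro_f1([row[4] for row in benchmarks.CPSC_FULL.values()])
print(f"CPSC2018 macro F1 from 9 per-class values: {cpsc_f1:.3f}")

no_cot = macro_f1([row[4] for row in benchmarks.PTBXL_NO_COT.values()])
print(f"PTB-XL macro F1 without the CoT block:     {no_cot:.3f}")

_, _, p, r, f1 = benchmarks.CPSC_FULL["AF"]
print(f"AF row: precision {p}, recall {r} -> F1 {f1_score(p, r):.3f} "
      f"(published {f1})")
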