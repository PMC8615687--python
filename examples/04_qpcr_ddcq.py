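"""Relative gene expression with the 2^-ddCq method.

Each sample contributes a target-gene Cq and a housekeeping-gene Cq;
the fold change is 2 to the minus (mean dCq treated - mean dCq control).
"""

from mrmlipid import QpcrSample, ddcq_fold_change

treated = [QpcrSample(cq_target=23.8, cq_reference=15.1),
           QpcrSample(cq_target=24.1, cq_reference=15.0)]
control = [QpcrSample(cq_target=24.6, cq_reference=15.2),
           QpcrSample(cq_target=24.9, cq_reference=15.1)]

fold = ddcq_fold_change(treated, control)
print(f"fold change = {fold:.2f}")
print("(> 1 means the target gene is upregulated in the treated samples "
      "relative to the housekeeping-normalized control)")
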