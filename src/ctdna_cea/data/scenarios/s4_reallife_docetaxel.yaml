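# Scenario 4: real-life Japanese second-line docetaxel (after abiraterone/
# enzalutamide) survival for both arms, instead of the first-line FIRSTANA
# docetaxel data of the base case (approximate real-world medians —
# NON-PAPER values).
id: s4_reallife_docetaxel
description: Real-life second-line docetaxel PFS/OS in both arms
overrides:
  lines.docetaxel.pfs.median: 6.4
  lines.docetaxel.os.median: 26.0
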