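# Scenario 2: cabazitaxel survival for the intervention arm from the
# PROSELICA trial (cabazitaxel 20 mg/m2 as second-line chemotherapy;
# medians transcribed from its primary publication — NON-PAPER values)
# instead of the CARD trial (third-line) used in the base case. Rationale:
# after a week-4 switch to docetaxel, cabazitaxel is effectively second-line
# chemotherapy.
id: s2_proselica_cabazitaxel
description: PROSELICA second-line cabazitaxel PFS/OS in the intervention arm
intervention_overrides:
  lines.cabazitaxel.pfs.median: 2.9
  lines.cabazitaxel.os.median: 13.4
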