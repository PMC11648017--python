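# Scenario 3: patients switching to docetaxel after 4 weeks in the
# intervention arm keep a higher quality of life (their condition has not
# yet deteriorated); docetaxel utility set to the mean of the abiraterone
# (0.80) and enzalutamide (0.81) utilities of the packaged base case.
id: s3_docetaxel_utility
description: Mean ARPI utility applied to docetaxel in the intervention arm
intervention_overrides:
  lines.docetaxel.utility: 0.805
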