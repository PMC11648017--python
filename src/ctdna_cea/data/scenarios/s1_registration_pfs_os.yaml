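# Scenario 1: the intervention arm's predicted durable responders use the
# same registration-trial PFS/OS as the standard-of-care arm (the
# durable-responder subgroup curves are dropped). The guided strategy then
# keeps only the switch-timing effect and the assay cost.
id: s1_registration_pfs_os
description: Registration-trial PFS/OS for durable responders (no subgroup advantage)
durable_equals_trial: true
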