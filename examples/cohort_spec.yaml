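# Sample cohort specification for `frnet simulate --spec examples/cohort_spec.yaml --out cohort/`
# Phenotype parameter blocks accept any PhenotypeParams field; omitted fields
# keep the responder / non-responder defaults.
n_responders: 21
n_nonresponders: 14
n_rns_nonresponders: 3
seed: 7
responder_params:
  duration_min: 60.0
nonresponder_params:
  duration_min: 60.0
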