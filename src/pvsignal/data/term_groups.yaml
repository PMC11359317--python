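# Composite adverse-event groups: label -> member preferred terms.
# Transcribed from the published CAR T-cell signal-detection tables'
# footnotes; users may extend or replace this file (validated at load:
# a PT may belong to at most one group).
Tremor:
  members:
    - Tremor
    - Intention tremor
    - Dystonic tremor
    - Resting tremor
    - Essential tremor
    - Action tremor
    - Postural tremor
  provenance: "key-organ AE table, footnote a"
Facial paralysis:
  members:
    - Facial paralysis
    - Facial paresis
  provenance: "key-organ AE table, footnote b"
Cytokine release syndrome:
  members:
    - Cytokine release syndrome
    - Cytokine storm
  provenance: "key-organ AE table, footnote c"
HLH:
  members:
    - HLH
    - Immune effector cell-associated HLH-like syndrome
  provenance: "key-organ AE table, footnote d"
Graft versus host disease:
  members:
    - Graft versus host disease
    - Acute graft versus host disease
    - Chronic graft versus host disease
    - Graft versus host disease in liver
    - Graft versus host disease in skin
  provenance: "key-organ AE table, footnote e"
Respiratory failure:
  members:
    - Respiratory failure
    - Acute respiratory failure
  provenance: "special-interest AE table, footnote a"
Pleural effusion:
  members:
    - Pleural effusion
    - Malignant pleural effusion
  provenance: "special-interest AE table, footnote b"
Tachycardia:
  members:
    - Tachycardia
    - Sinus tachycardia
    - Supraventricular tachycardia
    - Ventricular tachycardia
  provenance: "special-interest AE table, footnote c"
Hypotension:
  members:
    - Hypotension
    - Capillary leak syndrome
    - Orthostatic hypotension
  provenance: "special-interest AE table, footnote d"
Shock:
  members:
    - Shock
    - Haemorrhagic shock
    - Distributive shock
    - Hypovolaemic shock
    - Neurogenic shock
  provenance: "special-interest AE table, footnote e"
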