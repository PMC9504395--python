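# Default vaccine-aspect lexicon: three aspects, lowercase whole-token
# phrases.  "johnson amp johnson" is the HTML-escaped form of
# "Johnson & Johnson"; "johnson johnson" is what the tokenizer produces
# from the ampersand form, so both are listed.
vaccine_type:
  - pfizer
  - moderna
  - johnson amp johnson
  - johnson johnson
  - janssen
  - biotech
phased_vaccination:
  - frontline
  - phased
  - first dose
  - healthcare
  - old
  - second dose
  - operation
  - registration
  - cvs
  - pharmacy
  - administration
  - essential
  - medical condition
  - front line
  - health care
health_concern:
  - side effect
  - mask
  - die
  - warp speed
  - warp
  - fever
  - tiredness
  - headache
  - muscle pain
  - chills
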