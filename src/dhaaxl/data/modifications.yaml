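# Example modification config for dhaaxl.chem.load_modifications.
# Each entry: name, class (eliminylation|conjugate|label|fixed|
# crosslink_delta), targets (residue codes), and either gain/loss element
# maps or a bare mass (Da).  The built-in set already covers the DHAA
# chemistry; this file shows the format for extending it.
- name: NEM-DHAA
  class: conjugate
  targets: "ST"
  gain: {C: 6, H: 7, N: 1, O: 2}
  loss: {H: 2, O: 1}
- name: Oxidation
  class: conjugate
  targets: "M"
  gain: {O: 1}
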