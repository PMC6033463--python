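# Helix/coil segmentation of mature apoE4 (299 residues, 1-based).
# NT bundle helix boundaries beyond H4 follow the canonical apoE bundle
# literature; the CT domain is modeled as one long amphipathic helix with a
# flexible C-terminal tail.  All boundaries are overridable.
default:
  n_res: 299
  segments:
    - {label: nt_tail, start: 1,   end: 23,  ss: coil}
    - {label: H1,      start: 24,  end: 42,  ss: helix}
    - {label: L12,     start: 43,  end: 53,  ss: coil}
    - {label: H2,      start: 54,  end: 81,  ss: helix}
    - {label: L23,     start: 82,  end: 86,  ss: coil}
    - {label: H3,      start: 87,  end: 122, ss: helix}
    - {label: L34,     start: 123, end: 130, ss: coil}
    - {label: H4,      start: 131, end: 164, ss: helix}
    - {label: linker,  start: 165, end: 209, ss: coil}
    - {label: CT,      start: 210, end: 290, ss: helix}
    - {label: ct_tail, start: 291, end: 299, ss: coil}
  hinge_window: [186, 193]
  domains: {nt: [1, 191], ct: [210, 299]}

# Variant with helix 4 elongated to residue 180: the 164-168 stretch has
# converted to helix and merged with the short downstream helix (169-180).
elongated_h4:
  n_res: 299
  segments:
    - {label: nt_tail, start: 1,   end: 23,  ss: coil}
    - {label: H1,      start: 24,  end: 42,  ss: helix}
    - {label: L12,     start: 43,  end: 53,  ss: coil}
    - {label: H2,      start: 54,  end: 81,  ss: helix}
    - {label: L23,     start: 82,  end: 86,  ss: coil}
    - {label: H3,      start: 87,  end: 122, ss: helix}
    - {label: L34,     start: 123, end: 130, ss: coil}
    - {label: H4,      start: 131, end: 180, ss: helix}
    - {label: linker,  start: 181, end: 209, ss: coil}
    - {label: CT,      start: 210, end: 290, ss: helix}
    - {label: ct_tail, start: 291, end: 299, ss: coil}
  hinge_window: [186, 193]
  domains: {nt: [1, 191], ct: [210, 299]}
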