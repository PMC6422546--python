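[
  {
    "name": "BsmAI",
    "recognition": "GTCTC",
    "cut_top": 6,
    "cut_bottom": 10,
    "comment": "type IIS, GTCTC(1/5): top cut 1 nt downstream of the motif, bottom 5 nt"
  },
  {
    "name": "RsaI",
    "recognition": "GTAC",
    "cut_top": 2,
    "cut_bottom": 2,
    "comment": "blunt palindromic cutter GT^AC"
  },
  {
    "name": "BseYI",
    "recognition": "CCCAGC",
    "cut_top": 1,
    "cut_bottom": 5,
    "comment": "C^CCAGC, bottom strand cleaved after the 5th recognition base"
  }
]
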