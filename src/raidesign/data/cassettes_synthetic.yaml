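# Synthetic stand-in rAI cassettes; spans 0-based half-open.
cassettes:
  DECAI:
    recombinase: Cre
    site_spans: [[6, 40], [153, 187]]
    branchpoint_span: [148, 153]
    sha256: 88ad7b854c86883592e4af75f314d700d48fe3cc85276acaa1bf52237e3db53a
  AIv4:
    recombinase: Cre
    site_spans: [[6, 40], [153, 187]]
    branchpoint_span: [148, 153]
    sha256: 6a84690035ca3d455197b2493d6a424f90469d2028335bd6b3aab513e8494e78
  SCON-loxP:
    recombinase: Cre
    site_spans: [[7, 41], [141, 175]]
    branchpoint_span: [135, 140]
    sha256: a9badd3d2463cf220984b9f2a845d236418ccd5651705626c515c503b4e16d03
  SCON-FRT:
    recombinase: Flp
    site_spans: [[7, 41], [141, 175]]
    branchpoint_span: [135, 140]
    sha256: d61977d9a927d7b5306a106e4b87223d96c400d15027ecfe4fa1a47e24a26e91
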