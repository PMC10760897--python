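{
  "version": 1,
  "comment": "Regional current-density scale factors of the SAN pacemaker-conduction complex, relative to the central pacemaker compartment. i_kach encodes relative A1 adenosine receptor (IKACh) expression; i_k1 is the inward-rectifier addon present only in transitional (SACP) cells. Calibrated so that isolated center cells cycle at ~814 ms, head/tail at ~798 ms, and SACP cells are excitable but quiescent.",
  "regions": {
    "SAN_CENTER": {
      "i_na": 1.0,
      "i_f": 1.0,
      "i_k1": 0.0,
      "i_kach": 1.0
    },
    "SAN_HEAD": {
      "i_na": 10.0,
      "i_f": 0.8,
      "i_k1": 0.0,
      "i_kach": 0.1
    },
    "SAN_TAIL": {
      "i_na": 10.0,
      "i_f": 0.8,
      "i_k1": 0.0,
      "i_kach": 0.1
    },
    "SACP": {
      "i_na": 40.0,
      "i_f": 0.2,
      "i_k1": 0.3,
      "i_kach": 0.1
    },
    "RA": {
      "i_na": 1.0,
      "i_f": 0.0,
      "i_k1": 1.0,
      "i_kach": 1.0
    }
  },
  "hf_remodeling": {
    "comment": "Heart-failure electrical remodeling: fractional block applied on top of the control table, plus 20% fibrosis in SAN and SACP regions.",
    "i_f_block_san_sacp": 0.2,
    "i_na_block_san_sacp": 0.2,
    "i_na_block_ra": 0.05,
    "fibrosis_fraction_pct": 20.0
  }
}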