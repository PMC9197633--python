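# Example column map for a PPMI-style MDS-UPDRS export.
#
# Keys are the source file's column names; values are the canonical
# rating-field names of the packaged instrument definition. Pass this
# file to `load_assessments(..., mapping=...)` or `search --mapping`.
# The codes below follow the public PPMI variable-naming style; check
# them against the data dictionary of your actual export before use.
columns:
  PATNO: subject_id
  EVENT_ID: visit_id
  NHY: hy_stage
  # Part I - non-motor experiences of daily living
  NP1COG: "1.1"
  NP1HALL: "1.2"
  NP1DPRS: "1.3"
  NP1ANXS: "1.4"
  NP1APAT: "1.5"
  NP1DDS: "1.6"
  NP1SLPN: "1.7"
  NP1SLPD: "1.8"
  NP1PAIN: "1.9"
  NP1URIN: "1.10"
  NP1CNST: "1.11"
  NP1LTHD: "1.12"
  NP1FATG: "1.13"
  # Part II - motor experiences of daily living
  NP2SPCH: "2.1"
  NP2SALV: "2.2"
  NP2SWAL: "2.3"
  NP2EAT: "2.4"
  NP2DRES: "2.5"
  NP2HYGN: "2.6"
  NP2HWRT: "2.7"
  NP2HOBB: "2.8"
  NP2TURN: "2.9"
  NP2TRMR: "2.10"
  NP2RISE: "2.11"
  NP2WALK: "2.12"
  NP2FREZ: "2.13"
  # Part III - motor examination
  NP3SPCH: "3.1"
  NP3FACXP: "3.2"
  NP3RIGN: "3.3.neck"
  NP3RIGRU: "3.3.RUE"
  NP3RIGLU: "3.3.LUE"
  NP3RIGRL: "3.3.RLE"
  NP3RIGLL: "3.3.LLE"
  NP3FTAPR: "3.4.R"
  NP3FTAPL: "3.4.L"
  NP3HMOVR: "3.5.R"
  NP3HMOVL: "3.5.L"
  NP3PRSPR: "3.6.R"
  NP3PRSPL: "3.6.L"
  NP3TTAPR: "3.7.R"
  NP3TTAPL: "3.7.L"
  NP3LGAGR: "3.8.R"
  NP3LGAGL: "3.8.L"
  NP3RISNG: "3.9"
  NP3GAIT: "3.10"
  NP3FRZGT: "3.11"
  NP3PSTBL: "3.12"
  NP3POSTR: "3.13"
  NP3BRADY: "3.14"
  NP3PTRMR: "3.15.R"
  NP3PTRML: "3.15.L"
  NP3KTRMR: "3.16.R"
  NP3KTRML: "3.16.L"
  NP3RTARU: "3.17.RUE"
  NP3RTALU: "3.17.LUE"
  NP3RTARL: "3.17.RLE"
  NP3RTALL: "3.17.LLE"
  NP3RTALJ: "3.17.lipjaw"
  NP3RTCON: "3.18"
  # Part IV - motor complications
  NP4WDYSK: "4.1"
  NP4DYSKI: "4.2"
  NP4OFF: "4.3"
  NP4FLCTI: "4.4"
  NP4FLCTX: "4.5"
  NP4DYSTN: "4.6"
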