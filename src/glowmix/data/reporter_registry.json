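{
  "comment": "Registry of luciferase colour mutants x luciferin substrates. peak_nm are the in vitro peak emission wavelengths; fwhm_nm and skew parametrise the spectral shape model; photon_yield is relative photon output per cell (FLuc_natural + LH2 = 1).",
  "pairs": [
    {
      "enzyme": "FLuc_green",
      "substrate": "LH2",
      "peak_nm": 560,
      "fwhm_nm": 70,
      "skew": 0.25,
      "photon_yield": 1.0
    },
    {
      "enzyme": "FLuc_natural",
      "substrate": "LH2",
      "peak_nm": 560,
      "fwhm_nm": 70,
      "skew": 0.25,
      "photon_yield": 1.0
    },
    {
      "enzyme": "FLuc_red",
      "substrate": "LH2",
      "peak_nm": 620,
      "fwhm_nm": 70,
      "skew": 0.25,
      "photon_yield": 1.0
    },
    {
      "enzyme": "FLuc_green",
      "substrate": "iLH2",
      "peak_nm": 680,
      "fwhm_nm": 100,
      "skew": 0.8,
      "photon_yield": 0.01
    },
    {
      "enzyme": "FLuc_natural",
      "substrate": "iLH2",
      "peak_nm": 700,
      "fwhm_nm": 100,
      "skew": 0.8,
      "photon_yield": 0.01
    },
    {
      "enzyme": "FLuc_red",
      "substrate": "iLH2",
      "peak_nm": 720,
      "fwhm_nm": 100,
      "skew": 0.8,
      "photon_yield": 0.01
    },
    {
      "enzyme": "FLuc_green",
      "substrate": "CycLuc1",
      "peak_nm": 600,
      "fwhm_nm": 70,
      "skew": 0.25,
      "photon_yield": 1.0
    },
    {
      "enzyme": "FLuc_natural",
      "substrate": "CycLuc1",
      "peak_nm": 600,
      "fwhm_nm": 70,
      "skew": 0.25,
      "photon_yield": 1.0
    },
    {
      "enzyme": "FLuc_red",
      "substrate": "CycLuc1",
      "peak_nm": 600,
      "fwhm_nm": 70,
      "skew": 0.25,
      "photon_yield": 1.0
    },
    {
      "enzyme": "FLuc_green",
      "substrate": "AkaLumine",
      "peak_nm": 660,
      "fwhm_nm": 70,
      "skew": 0.25,
      "photon_yield": 1.0
    },
    {
      "enzyme": "FLuc_natural",
      "substrate": "AkaLumine",
      "peak_nm": 660,
      "fwhm_nm": 70,
      "skew": 0.25,
      "photon_yield": 1.0
    },
    {
      "enzyme": "FLuc_red",
      "substrate": "AkaLumine",
      "peak_nm": 660,
      "fwhm_nm": 70,
      "skew": 0.25,
      "photon_yield": 1.0
    }
  ]
}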