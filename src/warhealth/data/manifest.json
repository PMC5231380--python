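{
  "table2": {
    "file": "table2_national.csv",
    "source_table": "Table 2",
    "sha256": "7b8bb7efa7cf0a1f5e6c65c8de89d44f190cbb7f5fb6bec7525e5aa8b82af62f"
  },
  "table3": {
    "file": "table3_district_imr.csv",
    "source_table": "Table 3",
    "sha256": "655c54761e32bae13c6f9c2146ceefeee304fc38a719c7b6b0920bf4f76f097b"
  },
  "table4": {
    "file": "table4_imr_labels.csv",
    "source_table": "Table 4",
    "sha256": "81ec7fe6f819fe9c34412896a86b09f1eae27f6cafc46c1bda24a2af64e61d8f"
  },
  "table5": {
    "file": "table5_district_mmr.csv",
    "source_table": "Table 5",
    "sha256": "f57f769589455bdb3672af044dc0dd0e57177737e14b42aaecd3597a891bd6b1"
  },
  "table6": {
    "file": "table6_mmr_labels.csv",
    "source_table": "Table 6",
    "sha256": "bd9a1f45c99cde45743873efe2a16e233129f8ebaa8268d96becf66c0d1f2a2d"
  },
  "table9": {
    "file": "table9_impact_histogram.csv",
    "source_table": "Table 9",
    "sha256": "d35d36e84ed248f49c34e30f9d308df600ddc4afcb09f15c8736eaa9a0401bfb"
  },
  "unit_meta": {
    "file": "unit_meta.csv",
    "source_table": "Tables 3-6 groupings and endpoint footnotes",
    "sha256": "dd73620ff59f97a8a15669f1d39ebeb1d3b1000cba9c8833f146e327e72e8c73"
  }
}
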