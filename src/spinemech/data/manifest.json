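{
  "description": "Verbatim transcription of the study's printed summary tables; 'na' force entries are empty fields, NERH_5 carries broken=True.",
  "files": {
    "table1.csv": {
      "sha256": "2b9051efbef88b6e4cf38cc11d6ebc130041db0233f4bac4c1bbbd5a812e1d5b",
      "source": "per-species spine properties (printed summary table 1 of the genital-spine puncture study)",
      "row_labels": "species"
    },
    "table2.csv": {
      "sha256": "9c8da52641b8f43375f3ef7b066e42dc0a8744297493a4ae8b4f53c041f33516",
      "source": "per-spine puncture performance (printed summary table 2 of the genital-spine puncture study)",
      "row_labels": "spine_id"
    }
  }
}
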