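{
  "_comment": "Illustrative drug -> pharmacologically-active-target table for testing. Ligand matching is by InChIKey with exact ligand-id fallback. Production deployments supply their own full table.",
  "drugs": [
    {
      "name": "imatinib",
      "ligand_id": "STI",
      "inchikey": "KTUFNOKKBVMGRW-UHFFFAOYSA-N",
      "targets": ["P00519", "P10721", "P16234"]
    },
    {
      "name": "toy-drug",
      "ligand_id": "TOY",
      "inchikey": null,
      "targets": ["P99999"]
    }
  ]
}
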