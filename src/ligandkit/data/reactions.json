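{
  "_comment": "Illustrative reaction-participant table for testing (reaction id, participant structures, accessions of catalyzing proteins). Production deployments supply their own full table.",
  "reactions": [
    {
      "reaction_id": "RX:0001",
      "participants": [
        {"name": "ethanol", "smiles": "CCO"},
        {"name": "acetaldehyde", "smiles": "CC=O"},
        {"name": "NAD(+)", "smiles": "NC(=O)c1ccc[n+](c1)[C@@H]1O[C@H](COP(=O)([O-])OP(=O)(O)OC[C@H]2O[C@@H](n3cnc4c(N)ncnc43)[C@H](O)[C@@H]2O)[C@@H](O)[C@H]1O"},
        {"name": "NADH", "smiles": "NC(=O)C1=CN(C=CC1)[C@@H]1O[C@H](COP(=O)(O)OP(=O)(O)OC[C@H]2O[C@@H](n3cnc4c(N)ncnc43)[C@H](O)[C@@H]2O)[C@@H](O)[C@H]1O"}
      ],
      "protein_accessions": ["P00330", "P00329"]
    },
    {
      "reaction_id": "RX:0002",
      "participants": [
        {"name": "ATP", "smiles": "Nc1ncnc2c1ncn2[C@@H]1O[C@H](COP(=O)(O)OP(=O)(O)OP(=O)(O)O)[C@@H](O)[C@H]1O"},
        {"name": "ADP", "smiles": "Nc1ncnc2c1ncn2[C@@H]1O[C@H](COP(=O)(O)OP(=O)(O)O)[C@@H](O)[C@H]1O"},
        {"name": "D-glucose", "smiles": "OC[C@H]1OC(O)[C@H](O)[C@@H](O)[C@@H]1O"},
        {"name": "D-glucose 6-phosphate", "smiles": "OC1OC(COP(=O)(O)O)[C@@H](O)[C@H](O)[C@H]1O"}
      ],
      "protein_accessions": ["P35557"]
    }
  ]
}
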