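{
  "_comment": "Illustrative subset of organic cofactor classes for testing. Each class carries a template molecule, a representative molecule, a per-class minimum PARITY similarity threshold, and EC prefixes of the enzymes the class serves. Production deployments supply their own full table.",
  "classes": [
    {
      "name": "NAD",
      "template_smiles": "NC(=O)c1ccc[n+](c1)[C@@H]1O[C@H](COP(=O)([O-])OP(=O)(O)OC[C@H]2O[C@@H](n3cnc4c(N)ncnc43)[C@H](O)[C@@H]2O)[C@@H](O)[C@H]1O",
      "representative_smiles": "NC(=O)C1=CN(C=CC1)[C@@H]1O[C@H](COP(=O)(O)OP(=O)(O)OC[C@H]2O[C@@H](n3cnc4c(N)ncnc43)[C@H](O)[C@@H]2O)[C@@H](O)[C@H]1O",
      "threshold": 0.6,
      "ec": ["1.1.1", "1.2.1", "1.4.1", "1.6", "1.8.1"]
    },
    {
      "name": "FAD",
      "template_smiles": "Cc1cc2nc3c(=O)[nH]c(=O)n(CC(O)C(O)C(O)COP(=O)(O)OP(=O)(O)OC[C@H]4O[C@@H](n5cnc6c(N)ncnc65)[C@H](O)[C@@H]4O)c3nc2cc1C",
      "representative_smiles": "Cc1cc2nc3c(=O)[nH]c(=O)n(CC(O)C(O)C(O)COP(=O)(O)O)c3nc2cc1C",
      "threshold": 0.6,
      "ec": ["1.3", "1.5.1", "1.6.5", "1.8.3"]
    },
    {
      "name": "SAM",
      "template_smiles": "C[S+](CC[C@H](N)C(=O)[O-])C[C@H]1O[C@@H](n2cnc3c(N)ncnc32)[C@H](O)[C@@H]1O",
      "representative_smiles": "Nc1ncnc2c1ncn2[C@@H]1O[C@H](CSCC[C@H](N)C(=O)O)[C@@H](O)[C@H]1O",
      "threshold": 0.6,
      "ec": ["2.1.1"]
    },
    {
      "name": "Coenzyme A",
      "template_smiles": "CC(C)(COP(=O)(O)OP(=O)(O)OC[C@H]1O[C@@H](n2cnc3c(N)ncnc32)[C@H](O)[C@@H]1OP(=O)(O)O)C(O)C(=O)NCCC(=O)NCCS",
      "representative_smiles": "CC(=O)SCCNC(=O)CCNC(=O)C(O)C(C)(C)COP(=O)(O)OP(=O)(O)OC[C@H]1O[C@@H](n2cnc3c(N)ncnc32)[C@H](O)[C@@H]1OP(=O)(O)O",
      "threshold": 0.6,
      "ec": ["2.3.1", "6.2.1"]
    }
  ]
}
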