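{
  "name": "butyrate_formation",
  "description": "Butyrate formation from acetyl-CoA: eight enzymatic reactions covering both terminal routes (butyryl-CoA:acetate CoA-transferase, and phosphate butyryltransferase + butyrate kinase). Editable data, not code: amend the KO list to match the KEGG release in use.",
  "reactions": 8,
  "steps": [
    {"reaction": "acetyl-CoA -> acetoacetyl-CoA", "enzyme": "acetyl-CoA C-acetyltransferase (thiolase)", "kos": ["K00626"]},
    {"reaction": "acetoacetyl-CoA -> (S)-3-hydroxybutyryl-CoA", "enzyme": "3-hydroxybutyryl-CoA dehydrogenase (NADH)", "kos": ["K00074"]},
    {"reaction": "acetoacetyl-CoA -> (R)-3-hydroxybutyryl-CoA", "enzyme": "acetoacetyl-CoA reductase (NADPH)", "kos": ["K00023"]},
    {"reaction": "3-hydroxybutyryl-CoA -> crotonoyl-CoA", "enzyme": "enoyl-CoA hydratase / crotonase", "kos": ["K01692", "K01715"]},
    {"reaction": "crotonoyl-CoA -> butyryl-CoA", "enzyme": "butyryl-CoA dehydrogenase", "kos": ["K00248"]},
    {"reaction": "butyryl-CoA + acetate -> butyrate + acetyl-CoA", "enzyme": "butyryl-CoA:acetate CoA-transferase", "kos": ["K01034", "K01035", "K18118"]},
    {"reaction": "butyryl-CoA -> butyryl-phosphate", "enzyme": "phosphate butyryltransferase", "kos": ["K00634"]},
    {"reaction": "butyryl-phosphate -> butyrate", "enzyme": "butyrate kinase", "kos": ["K00929"]}
  ],
  "kos": ["K00626", "K00074", "K00023", "K01692", "K01715", "K00248", "K01034", "K01035", "K18118", "K00634", "K00929"]
}
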