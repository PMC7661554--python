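# Default amino-acid catabolic pathway catalog (best-effort reconstruction
# from literature-standard anaerobic/fermentative routes; users may supply
# their own catalog file). One entry per (aa, pathway_id); a pathway is
# complete only when every listed gene symbol is present in a genome.
- aa: alanine
  pathway_id: alanine_dehydrogenase
  product: pyruvate
  genes: [ald]
  ec: ["1.4.1.1"]
- aa: alanine
  pathway_id: alanine_transaminase
  product: pyruvate
  genes: [alaT]
  ec: ["2.6.1.2"]
- aa: arginine
  pathway_id: arginine_deiminase
  product: ornithine + carbamoyl phosphate
  genes: [arcA, arcB, arcC]
  ec: ["3.5.3.6", "2.1.3.3", "2.7.2.2"]
- aa: asparagine
  pathway_id: asparagine_to_fumarate
  product: fumarate
  genes: [ansA, aspA]
  ec: ["3.5.1.1", "4.3.1.1"]
- aa: aspartate
  pathway_id: aspartate_ammonia_lyase
  product: fumarate
  genes: [aspA]
  ec: ["4.3.1.1"]
- aa: cysteine
  pathway_id: cysteine_desulfhydrase
  product: pyruvate
  genes: [dcyD]
  ec: ["4.4.1.15"]
- aa: glutamate
  pathway_id: glutamate_dehydrogenase
  product: 2-oxoglutarate
  genes: [gdhA]
  ec: ["1.4.1.2"]
- aa: glutamine
  pathway_id: glutamine_gogat
  product: glutamate
  genes: [gltB, gltD]
  ec: ["1.4.1.13"]
- aa: glycine
  pathway_id: glycine_decarboxylating
  product: pyruvate
  genes: [gcvPA, gcvPB, gcvH, gcvT, lpd, glyA]
  ec: ["1.4.4.2", "2.1.2.10", "1.8.1.4", "2.1.2.1"]
- aa: glycine
  pathway_id: glycine_reductase
  product: acetyl phosphate
  genes: [grdA, grdB, grdC, grdD, grdE]
  ec: ["1.21.4.2"]
- aa: histidine
  pathway_id: histidine_hut
  product: glutamate
  genes: [hutH, hutU, hutI, hutG, folD]
  ec: ["4.3.1.3", "4.2.1.49", "3.5.2.7", "3.5.3.8", "3.5.4.9"]
- aa: isoleucine
  pathway_id: isoleucine_oxidative
  product: 2-methylbutyryl-CoA
  genes: [ilvE, bkdA, bkdB, bkdC]
  ec: ["2.6.1.42", "1.2.7.7"]
- aa: leucine
  pathway_id: leucine_oxidative
  product: isovaleryl-CoA
  genes: [ilvE, bkdA, bkdB, bkdC]
  ec: ["2.6.1.42", "1.2.7.7"]
- aa: lysine
  pathway_id: lysine_fermentative
  product: butyrate + acetate
  genes: [kamA, kamD, kamE, kdd, kce, kal, bcd, atoD]
  ec: ["5.4.3.2", "5.4.3.3", "1.4.1.11", "2.3.1.247", "4.3.1.14"]
- aa: methionine
  pathway_id: methionine_gamma_lyase
  product: propionyl-CoA + methanethiol
  genes: [mgl, pflB]
  ec: ["4.4.1.11", "2.3.1.54"]
- aa: phenylalanine
  pathway_id: phenylalanine_reductive
  product: phenylacetate
  genes: [aroT, iorA, iorB]
  ec: ["2.6.1.57", "1.2.7.8"]
- aa: proline
  pathway_id: proline_oxidative
  product: glutamate
  genes: [putB, putA]
  ec: ["1.5.5.2", "1.2.1.88"]
- aa: serine
  pathway_id: serine_dehydratase
  product: pyruvate
  genes: [sdaA]
  ec: ["4.3.1.17"]
- aa: threonine
  pathway_id: threonine_aldolase
  product: glycine + acetaldehyde
  genes: [ltaE]
  ec: ["4.1.2.48"]
- aa: threonine
  pathway_id: threonine_dehydrogenase
  product: glycine + acetyl-CoA
  genes: [tdh, kbl]
  ec: ["1.1.1.103", "2.3.1.29"]
- aa: threonine
  pathway_id: threonine_ammonia_lyase
  product: 2-oxobutyrate
  genes: [tdcB]
  ec: ["4.3.1.19"]
- aa: tryptophan
  pathway_id: tryptophanase
  product: indole + pyruvate
  genes: [tnaA]
  ec: ["4.1.99.1"]
- aa: tyrosine
  pathway_id: tyrosine_reductive
  product: 4-hydroxyphenylacetate
  genes: [tyrB, iorA, iorB]
  ec: ["2.6.1.5", "1.2.7.8"]
- aa: valine
  pathway_id: valine_oxidative
  product: isobutyryl-CoA
  genes: [ilvE, bkdA, bkdB, bkdC]
  ec: ["2.6.1.42", "1.2.7.7"]
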