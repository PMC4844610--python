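{
 "name": "truth_table",
 "comment": "32 experimental manipulations of the rodent food-intake control system and their observed outcomes (statistically significant increase/decrease/excitation/inhibition, or no significant change). Experiments 1-25 score food intake only; 26-32 also score POMC/AgRP/OXT neural activity where measured.",
 "experiments": [
  {"id": 1, "label": "POMC knockout", "manipulations": ["lesion:POMC"], "expected": {"FI": "increase"}},
  {"id": 2, "label": "MC3R knockout", "manipulations": ["zero_receptor:*:MC3R"], "expected": {"FI": "increase"}},
  {"id": 3, "label": "MC4R knockout", "manipulations": ["zero_receptor:*:MC4R"], "expected": {"FI": "increase"}},
  {"id": 4, "label": "Y1R knockout", "manipulations": ["zero_receptor:*:Y1R"], "expected": {"FI": "decrease"}},
  {"id": 5, "label": "db/db or ob/ob (loss of leptin signaling)", "manipulations": ["set_substance:leptin:0"], "expected": {"FI": "increase"}},
  {"id": 6, "label": "LepRB deletion in POMC neurons", "manipulations": ["zero_receptor:POMC:LepRB"], "expected": {"FI": "no_change"}},
  {"id": 7, "label": "LepRB deletion in AgRP neurons", "manipulations": ["zero_receptor:AgRP:LepRB"], "expected": {"FI": "no_change"}},
  {"id": 8, "label": "LepRB deletion in POMC and AgRP neurons", "manipulations": ["zero_receptor:POMC:LepRB", "zero_receptor:AgRP:LepRB"], "expected": {"FI": "no_change"}},
  {"id": 9, "label": "LepRB deletion in NTS neurons", "manipulations": ["zero_receptor:NTSCA:LepRB", "zero_receptor:NTSGLP1:LepRB"], "expected": {"FI": "increase"}},
  {"id": 10, "label": "LepRB deletion in GABAergic neurons", "manipulations": ["zero_receptor:AgRP:LepRB", "zero_receptor:NGABA:LepRB", "zero_receptor:LHGal:LepRB", "zero_receptor:NT:LepRB"], "expected": {"FI": "increase"}},
  {"id": 11, "label": "LepRB expressed only in POMC neurons", "manipulations": ["zero_receptor:AgRP:LepRB", "zero_receptor:NGABA:LepRB", "zero_receptor:LHGal:LepRB", "zero_receptor:NT:LepRB", "zero_receptor:NTSCA:LepRB", "zero_receptor:NTSGLP1:LepRB", "zero_receptor:VTA:LepRB"], "expected": {"FI": "increase"}},
  {"id": 12, "label": "5HT1B receptor knockout", "manipulations": ["zero_receptor:*:5HT1BR"], "expected": {"FI": "no_change"}},
  {"id": 13, "label": "5HT2C receptor knockout", "manipulations": ["zero_receptor:*:5HT2CR"], "expected": {"FI": "increase"}},
  {"id": 14, "label": "Photo-stimulation of AgRP neurons", "manipulations": ["stim_soma:AgRP"], "expected": {"FI": "increase"}},
  {"id": 15, "label": "Photo-stimulation of AgRP projection to PVH", "manipulations": ["stim_projection:AgRP:OXT"], "expected": {"FI": "increase"}},
  {"id": 16, "label": "Photo-stimulation of AgRP projection to PVH and photo-stimulation of PVH", "manipulations": ["stim_projection:AgRP:OXT", "stim_soma:OXT"], "expected": {"FI": "no_change"}},
  {"id": 17, "label": "Photo-stimulation of AgRP neurons and chemo-inhibition of AgRP projection to PVH", "manipulations": ["stim_soma:AgRP", "block_projection:AgRP:OXT"], "expected": {"FI": "increase"}},
  {"id": 18, "label": "Photo-stimulation of AgRP projection to PVH while blocking GABA receptors on PVH", "manipulations": ["stim_projection:AgRP:OXT", "zero_receptor:OXT:GABAR"], "expected": {"FI": "no_change"}},
  {"id": 19, "label": "Photo-stimulation of AgRP projection to PVH while blocking Y1R receptors on PVH", "manipulations": ["stim_projection:AgRP:OXT", "zero_receptor:OXT:Y1R"], "expected": {"FI": "no_change"}},
  {"id": 20, "label": "Chemogenetic activation of AgRP neurons while blocking GABA receptors on PVH", "manipulations": ["stim_soma:AgRP", "zero_receptor:OXT:GABAR"], "expected": {"FI": "increase"}},
  {"id": 21, "label": "Chemogenetic activation of AgRP neurons while blocking Y1R receptors on PVH", "manipulations": ["stim_soma:AgRP", "zero_receptor:OXT:Y1R"], "expected": {"FI": "increase"}},
  {"id": 22, "label": "Chemo-inhibition of AgRP neurons", "manipulations": ["inhibit_soma:AgRP"], "expected": {"FI": "decrease"}},
  {"id": 23, "label": "Photo-stimulation of AgRP and POMC neurons", "manipulations": ["stim_soma:AgRP", "stim_soma:POMC"], "expected": {"FI": "increase"}},
  {"id": 24, "label": "Chemo-inhibition of PVH neurons", "manipulations": ["inhibit_soma:OXT"], "expected": {"FI": "increase"}},
  {"id": 25, "label": "Photo-stimulation of AgRP projection to LH", "manipulations": ["stim_projection:AgRP:OX"], "expected": {"FI": "increase"}},
  {"id": 26, "label": "Leptin administration", "manipulations": ["set_substance:leptin:2"], "expected": {"FI": "decrease", "POMC": "excitation", "AgRP": "inhibition", "OXT": "excitation"}},
  {"id": 27, "label": "Ghrelin administration", "manipulations": ["set_substance:ghrelin:2"], "expected": {"FI": "increase", "POMC": "inhibition", "AgRP": "excitation"}},
  {"id": 28, "label": "5HT1B receptor agonist administration", "manipulations": ["set_drug:agonist_5ht1b:1"], "expected": {"AgRP": "inhibition"}},
  {"id": 29, "label": "5HT2C receptor agonist administration", "manipulations": ["set_drug:agonist_5ht2c:1"], "expected": {"FI": "decrease", "POMC": "excitation"}},
  {"id": 30, "label": "alpha-MSH administration", "manipulations": ["set_drug:exo_amsh:1"], "expected": {"FI": "decrease", "OXT": "excitation"}},
  {"id": 31, "label": "Glucose administration", "manipulations": ["set_substance:glucose:2"], "expected": {"FI": "no_change"}},
  {"id": 32, "label": "GLP-1 administration", "manipulations": ["set_drug:exo_glp1:1"], "expected": {"FI": "decrease"}}
 ]
}
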