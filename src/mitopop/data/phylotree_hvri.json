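{
 "description": "Reduced synthetic haplogroup tree over the HVRI window. Defining variants are loosely modelled on classic control-region motifs but the tree is a small stand-in for testing and simulation, not an excerpt of the full mtDNA phylogeny.",
 "nodes": {
  "ROOT": {"parent": null, "variants": []},
  "H": {"parent": "ROOT", "variants": ["16080G"]},
  "H1cf": {"parent": "H", "variants": ["16213A"]},
  "H4a1e": {"parent": "H", "variants": ["16300G"]},
  "HV0": {"parent": "ROOT", "variants": ["16298C"]},
  "J": {"parent": "ROOT", "variants": ["16069T", "16126C"]},
  "K": {"parent": "ROOT", "variants": ["16224C", "16311C"]},
  "L1b": {"parent": "ROOT", "variants": ["16187T", "16223T", "16264T"]},
  "L2": {"parent": "ROOT", "variants": ["16223T", "16390A"]},
  "L3": {"parent": "ROOT", "variants": ["16223T"]},
  "L3b": {"parent": "L3", "variants": ["16124C", "16278T"]},
  "L3b1a12": {"parent": "L3b", "variants": ["16212G"]},
  "M1": {"parent": "L3", "variants": ["16249C"]},
  "T": {"parent": "ROOT", "variants": ["16126C", "16294T"]},
  "T2c1": {"parent": "T", "variants": ["16292T", "16296T"]},
  "U5": {"parent": "ROOT", "variants": ["16192T", "16270T"]},
  "U6": {"parent": "ROOT", "variants": ["16172C", "16219G"]},
  "U6a": {"parent": "U6", "variants": ["16278T"]},
  "U6b": {"parent": "U6", "variants": ["16311C"]},
  "U6b1a": {"parent": "U6b", "variants": ["16163G"]},
  "U6b1a1": {"parent": "U6b1a", "variants": ["@16311"]},
  "U6c": {"parent": "U6", "variants": ["16169T"]},
  "U7": {"parent": "ROOT", "variants": ["16318T"]},
  "W1e1": {"parent": "ROOT", "variants": ["16223T", "16292T", "16320T"]},
  "X3a": {"parent": "ROOT", "variants": ["16189C", "16223T", "16248T"]}
 }
}
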