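# Synthetic, illustrative calibration set for the example tree-of-life
# topology (species_tree_topology_synthetic.nwk).  It reconstructs the
# *shape* of a cross-braced dating configuration — a hard root maximum at
# the moon-forming impact, geochemical minima for oxygenic photosynthesis,
# Proterozoic algal fossil minima applied to every eukaryotic genome copy,
# braces tying the equivalent nodes of the nuclear/mitochondrial/plastid
# clades, and the relative constraint that crown plastids postdate the
# eukaryote crown.  Ages are in Ma; numeric values are plausible
# placeholders, not a curated fossil calibration scholarship.
calibrations:
  - name: root_luca
    taxa: [Halobacterium, Escherichia]      # spans both domains -> root
    min: 3347
    max: 4520                                # moon-forming impact
    steepness_min: 100
    steepness_max: 10                        # effectively hard
  - name: crown_bacteria
    taxa: [Escherichia, Bacillus, Synechocystis]
    min: 3200
    steepness_min: 100
  - name: crown_archaea
    taxa: [Halobacterium, Sulfolobus, Lokiarchaeum]
    min: 3000
    steepness_min: 120
  - name: oxygenic_cyanobacteria
    taxa: [Gloeomargarita, Synechocystis, Arabidopsis_plastid]
    min: 2320                                # great oxidation event
    steepness_min: 60
  - name: leca_nuclear
    taxa: [Homo_nuclear, Arabidopsis_nuclear]
    min: 1030
    max: 1891
    steepness_min: 25
    steepness_max: 50
  - name: leca_mitochondrial
    taxa: [Homo_mito, Arabidopsis_mito]
    min: 1030
    max: 1891
    steepness_min: 25
    steepness_max: 50
  - name: crown_archaeplastida_nuclear
    taxa: [Arabidopsis_nuclear, Cyanidioschyzon_nuclear]
    min: 1030                                # Bangiomorpha pubescens
    steepness_min: 25
  - name: crown_archaeplastida_mitochondrial
    taxa: [Arabidopsis_mito, Cyanidioschyzon_mito]
    min: 1030
    steepness_min: 25
  - name: crown_archaeplastida_plastid
    taxa: [Arabidopsis_plastid, Cyanidioschyzon_plastid]
    min: 1030
    steepness_min: 25
  - name: mito_alpha_ancestor
    taxa: [Rickettsia, Homo_mito]
    max: 2580
    steepness_max: 65
  - name: plastid_cyano_ancestor
    taxa: [Synechocystis, Arabidopsis_plastid]
    max: 2140
    steepness_max: 55
  - name: euk_asgard_ancestor
    taxa: [Heimdallarchaeum, Homo_nuclear]
    max: 2670
    steepness_max: 65
braces:
  - name: leca
    groups:
      - [Homo_nuclear, Saccharomyces_nuclear, Arabidopsis_nuclear, Cyanidioschyzon_nuclear]
      - [Homo_mito, Saccharomyces_mito, Arabidopsis_mito, Cyanidioschyzon_mito]
    sigma: 4.5
  - name: crown_archaeplastida
    groups:
      - [Arabidopsis_nuclear, Cyanidioschyzon_nuclear]
      - [Arabidopsis_mito, Cyanidioschyzon_mito]
      - [Arabidopsis_plastid, Cyanidioschyzon_plastid]
    sigma: 4.5
older_than:
  - name: plastid_crown_younger_than_nuclear_leca
    younger: [Arabidopsis_plastid, Cyanidioschyzon_plastid]
    older: [Homo_nuclear, Saccharomyces_nuclear, Arabidopsis_nuclear, Cyanidioschyzon_nuclear]
    softness: 10
  - name: plastid_crown_younger_than_mitochondrial_leca
    younger: [Arabidopsis_plastid, Cyanidioschyzon_plastid]
    older: [Homo_mito, Saccharomyces_mito, Arabidopsis_mito, Cyanidioschyzon_mito]
    softness: 10
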