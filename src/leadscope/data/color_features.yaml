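# Default pharmacophore color-feature ruleset.
#
# Polar and ionic kinds are SMARTS driven; the first atom of each match
# anchors donor/acceptor features, while anion/cation features sit at the
# centroid of the whole matched group.  Ring features (SSSR centroids) and
# hydrophobes (connected all-carbon clusters) are algorithmic and only
# parameterized here.  Atoms matched by an ionic pattern are excluded from
# donor/acceptor typing so a carboxylate is one anion, not an anion plus
# two acceptors.
#
# Ionization state reflects pH 7.4: carboxylic acids count as anions,
# aliphatic amines and amidine/guanidine groups as cations, in addition to
# explicitly charged atoms.

radius: 1.0

donor:
  smarts:
    - "[#7;!H0]"          # N-H
    - "[#8;!H0]"          # O-H

acceptor:
  smarts:
    - "[#8;X1,X2]"        # carbonyl / ether / hydroxyl oxygen
    - "[#7;X1,X2]"        # nitrile / imine / pyridine-type nitrogen
    - "[n;X2]"            # aromatic N with lone pair

anion:
  smarts:
    - "[CX3](=[OX1])[OX1-]"     # carboxylate
    - "[CX3](=[OX1])[OX2H1]"    # carboxylic acid (deprotonated at pH 7.4)
    - "[SX4](=O)(=O)[OX1-,OX2H1]"
    - "[O-,S-;!$([O-]C=O)]"     # other explicitly charged O/S

cation:
  smarts:
    - "[NX4+]"                   # quaternary / protonated amine
    - "[NX3+]"
    - "[NX3][CX3]=[NX3+0,NX3+1]" # amidine / guanidine
    - "[+1;!$([NX3][CX3]=[NX3])]"

hydrophobe:
  min_cluster_size: 2

ring: {}
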