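# Five-lobe grouping of the 34 standard cortical parcellation labels per
# hemisphere.  Membership follows the FreeSurfer cortical-parcellation
# guideline; the insula is placed with the frontal group to keep five lobes
# per hemisphere.  This file is editable data: adjust memberships freely.
lobes:
  frontal:
    - superiorfrontal
    - rostralmiddlefrontal
    - caudalmiddlefrontal
    - parsopercularis
    - parstriangularis
    - parsorbitalis
    - lateralorbitofrontal
    - medialorbitofrontal
    - precentral
    - paracentral
    - frontalpole
    - insula
  parietal:
    - superiorparietal
    - inferiorparietal
    - supramarginal
    - postcentral
    - precuneus
  temporal:
    - superiortemporal
    - middletemporal
    - inferiortemporal
    - bankssts
    - fusiform
    - transversetemporal
    - entorhinal
    - temporalpole
    - parahippocampal
  occipital:
    - lateraloccipital
    - lingual
    - cuneus
    - pericalcarine
  cingulate:
    - rostralanteriorcingulate
    - caudalanteriorcingulate
    - posteriorcingulate
    - isthmuscingulate
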