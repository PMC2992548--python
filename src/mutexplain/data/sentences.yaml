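# Sentence templates for decision-scheme findings.  Decision logic is kept
# apart from phrasing; templates use str.format placeholders filled from
# the analysis context.  Keys are referenced by rules.yaml.

disulfide_lost: >-
  The wild-type {wild_name} at position {position} forms a disulfide bond
  ({disulfide_detail}). The mutant {mutant_name} cannot form this disulfide
  bond, the loss of which will destabilize the structure.

salt_bridge_broken: >-
  The wild-type {wild_name} at position {position} is involved in a salt
  bridge ({salt_bridge_detail}). The substitution to {mutant_name} changes
  the charge at this position ({charge_label}), which will disturb this
  ionic interaction.

ligand_contact_disturbed: >-
  Residue {position} is in direct contact with {ligand_names}. The
  difference in properties between {wild_name} and {mutant_name}
  ({change_summary}) can disturb this interaction.

sidechain_hbond_lost: >-
  The wild-type {wild_name} at position {position} makes a hydrogen bond
  that the mutant {mutant_name} side chain cannot maintain, which can
  affect local stability or interactions.

transmem_charge: >-
  Position {position} lies in a transmembrane domain ({region_detail}).
  The mutation introduces a charge ({charge_label}) into the membrane-
  embedded segment, which can disturb membrane insertion or helix packing.

transmem_hydrophobicity: >-
  Position {position} lies in a transmembrane domain ({region_detail}).
  The mutation changes the hydrophobicity at this position
  ({hydrophobicity_label}, {d_hydrophobicity:+.1f}), which matters in the
  membrane environment.

active_site: >-
  Position {position} is annotated as functionally critical
  ({region_detail}). Any substitution here, including {wild_name} to
  {mutant_name}, is likely to affect the protein's activity.

helix_breaker: >-
  Position {position} is located in an alpha-helix. The mutant
  {mutant_name} disrupts alpha-helices, so this substitution is likely to
  break the helix and thereby the local structure.

strand_proline: >-
  Position {position} is located in a beta-strand. Proline cannot adopt
  the backbone conformation of a strand and will disturb this
  secondary-structure element.

named_region: >-
  Position {position} lies in an annotated region ({region_detail}); a
  substitution here can affect the function associated with this region.

phospho_lost: >-
  The wild-type {wild_name} at position {position} is a phosphorylation
  site. The mutant {mutant_name} cannot accept a phosphate group, so this
  modification is abolished, which can disturb signalling.

phospho_kept: >-
  Position {position} is a phosphorylation site. The mutant {mutant_name}
  can still accept a phosphate group, so the site may still be modified,
  although kinase recognition can be affected.

variant_same: >-
  The substitution {wild}{position}{mutant} has been described before at
  this position ({variant_detail}).

variant_other: >-
  Other variation is known at position {position} ({variant_detail}),
  which can help interpret the present substitution.

conservation_severe: >-
  Position {position} is {conservation_word} in the multiple sequence
  alignment (wild-type frequency {wild_freq_pct}%), and {mutant_name} was
  never observed there. Mutation of such a conserved residue is likely to
  be damaging.

conservation_moderate: >-
  Position {position} is conserved in the multiple sequence alignment
  (wild-type frequency {wild_freq_pct}%). The substitution to
  {mutant_name} (observed frequency {mutant_freq_pct}%) may not be
  tolerated.

conservation_variable: >-
  Position {position} is variable in the multiple sequence alignment, and
  {mutant_name} occurs in homologues (frequency {mutant_freq_pct}%), so
  the substitution is more likely to be tolerated.

core_destabilization: >-
  The mutation introduces a less hydrophobic residue in the core of the
  protein which can destabilize the structure.

core_clash: >-
  The mutant {mutant_name} is bigger than the wild-type {wild_name}
  ({d_volume:+.1f} cubic Angstrom) and position {position} is buried in a
  tightly packed environment; the larger side chain probably does not fit,
  which can destabilize the structure.

core_charge: >-
  The mutation introduces a charge ({charge_label}) at buried position
  {position}; burying an unsatisfied charge in the protein core is
  strongly destabilizing.

surface_change: >-
  Position {position} is on the protein surface. The substitution changes
  residue properties ({change_summary}); surface positions usually
  tolerate this, but interactions with other molecules could be affected.

property_summary: >-
  The wild-type residue is {wild_name} and the mutant residue is
  {mutant_name}. {change_sentence}
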