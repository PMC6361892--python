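# Default ADI-R item sets for restricted-and-repetitive-behaviour subtypes.
#
# These are literature-derived defaults (factor-analytic groupings of the
# ADI-R RRB-domain items commonly used to score Repetitive Motor Behaviours,
# Insistence on Sameness and Circumscribed Interests); edit to match the item
# columns of your own cohort table.  Item ids refer to ADI-R "ever" score
# columns named adi_<item number>.
repetitive_motor_behaviours:
  - adi_69   # repetitive use of objects
  - adi_71   # unusual sensory interests
  - adi_77   # hand and finger mannerisms
  - adi_78   # other complex mannerisms or stereotyped body movements
insistence_on_sameness:
  - adi_70   # compulsions and rituals
  - adi_74   # difficulties with minor changes in routine
  - adi_75   # resistance to trivial changes in the environment
circumscribed_interests:
  - adi_67   # unusual preoccupations
  - adi_68   # circumscribed interests
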