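british,american
analyse,analyze
analysed,analyzed
analyses,analyzes
analysing,analyzing
anaemia,anemia
anaesthesia,anesthesia
behaviour,behavior
behavioural,behavioral
behaviours,behaviors
catalogue,catalog
centre,center
centres,centers
colour,color
coloured,colored
colours,colors
counselling,counseling
defence,defense
dialogue,dialog
emphasise,emphasize
emphasised,emphasized
favour,favor
favourable,favorable
fibre,fiber
foetal,fetal
foetus,fetus
generalise,generalize
generalised,generalized
generalisation,generalization
grey,gray
haemorrhage,hemorrhage
haemodynamic,hemodynamic
hypothesise,hypothesize
hypothesised,hypothesized
labelled,labeled
labelling,labeling
licence,license
litre,liter
localisation,localization
localised,localized
maximise,maximize
metre,meter
minimise,minimize
modelled,modeled
modelling,modeling
neighbour,neighbor
normalise,normalize
normalised,normalized
oedema,edema
oestrogen,estrogen
organisation,organization
organise,organize
organised,organized
paediatric,pediatric
paralyse,paralyze
practise,practice
programme,program
randomise,randomize
randomised,randomized
randomisation,randomization
recognise,recognize
recognised,recognized
signalling,signaling
standardised,standardized
standardisation,standardization
summarise,summarize
summarised,summarized
theatre,theater
tumour,tumor
tumours,tumors
utilise,utilize
utilised,utilized
visualisation,visualization
visualised,visualized
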