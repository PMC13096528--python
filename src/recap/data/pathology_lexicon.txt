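# Default pathology lexicon: one term per line, '#' starts a comment.
# Multi-word terms are matched before their sub-terms.
# --- nuclear / cytologic features ---
nuclear pleomorphism
pleomorphism
nuclear atypia
atypia
hyperchromasia
hyperchromatic nuclei
prominent nucleoli
nucleoli
coarse chromatin
vesicular chromatin
chromatin clumping
nuclear enlargement
nuclear crowding
nuclear overlap
irregular nuclear contours
nuclear grooves
intranuclear inclusions
high nuclear to cytoplasmic ratio
binucleation
multinucleated giant cells
anisonucleosis
karyorrhexis
pyknosis
# --- mitotic activity ---
mitotic figures
mitotic activity
atypical mitoses
high mitotic index
proliferative activity
# --- architecture ---
cribriform architecture
cribriform
micropapillary pattern
papillary architecture
solid growth pattern
tubular formation
glandular differentiation
gland formation
acinar structures
trabecular pattern
nested architecture
lobular architecture
loss of polarity
architectural distortion
back to back glands
fused glands
single file infiltration
indian file pattern
sheets of cells
comedo pattern
roman bridge formation
secondary lumens
# --- invasion / stroma ---
stromal invasion
invasive front
infiltrative growth
infiltrative border
pushing border
desmoplasia
desmoplastic stroma
stromal reaction
perineural invasion
lymphovascular invasion
vascular invasion
capsular invasion
fat invasion
skeletal muscle invasion
basement membrane disruption
myoepithelial layer loss
retraction artifact
elastosis
# --- in situ / ductal ---
ductal confinement
intact ducts
intraductal proliferation
ductal carcinoma in situ
comedo necrosis
central necrosis
punctate necrosis
duct ectasia
pagetoid spread
lobular neoplasia
atypical ductal hyperplasia
usual ductal hyperplasia
columnar cell change
apocrine metaplasia
flat epithelial atypia
# --- necrosis / secretions ---
tumor necrosis
coagulative necrosis
geographic necrosis
luminal secretions
mucin production
extracellular mucin
mucinous differentiation
signet ring cells
# --- inflammation / microenvironment ---
lymphocytic infiltrate
tumor infiltrating lymphocytes
chronic inflammation
acute inflammation
plasma cells
histiocytes
foamy macrophages
granuloma formation
stromal edema
fibrosis
hyalinization
sclerosis
calcifications
microcalcifications
psammoma bodies
hemorrhage
hemosiderin deposition
# --- cell types / cytoplasm ---
spindle cells
epithelioid cells
clear cell change
eosinophilic cytoplasm
granular cytoplasm
squamous differentiation
keratinization
keratin pearls
intercellular bridges
goblet cells
columnar epithelium
cuboidal epithelium
stratified epithelium
myoepithelial cells
basal cells
# --- prostate-oriented ---
gleason pattern
small acini
fused acini
poorly formed glands
glomeruloid structures
perineural wrapping
prostatic intraepithelial neoplasia
basal cell layer loss
blue mucin
crystalloids
# --- general malignancy descriptors ---
anaplasia
dedifferentiation
tumor budding
satellite nodules
multifocality
tumor heterogeneity
cellular discohesion
apoptotic bodies
apoptosis
dysplasia
severe dysplasia
carcinoma in situ
microinvasion
margin involvement
extracapsular extension
# --- benign / normal descriptors ---
normal lobular architecture
uniform nuclei
bland cytology
regular gland spacing
preserved polarity
thin fibrous septa
adipose tissue
terminal duct lobular unit
stromal hyalinization
benign epithelium
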