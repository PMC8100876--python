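# Disease/observation lexicon for the synthetic corpus generator.
# One condition per line; multiword terms exercise partial span matching.
diabetes
type 2 diabetes
type 1 diabetes
gestational diabetes
hypertension
high blood pressure
breast cancer
colon cancer
lung cancer
prostate cancer
ovarian cancer
pancreatic cancer
esophageal cancer
stomach cancer
skin cancer
melanoma
leukemia
lymphoma
heart disease
coronary artery disease
congestive heart failure
atrial fibrillation
heart attack
myocardial infarction
stroke
transient ischemic attack
asthma
chronic bronchitis
emphysema
pneumonia
tuberculosis
arthritis
rheumatoid arthritis
osteoarthritis
osteoporosis
gout
lupus
multiple sclerosis
parkinson disease
alzheimer disease
dementia
epilepsy
seizure disorder
migraine headaches
depression
bipolar disorder
anxiety disorder
schizophrenia
autism
attention deficit disorder
obesity
high cholesterol
hyperlipidemia
thyroid disease
hypothyroidism
hyperthyroidism
goiter
kidney disease
chronic kidney disease
kidney stones
polycystic kidney disease
liver disease
cirrhosis
hepatitis b
hepatitis c
fatty liver disease
celiac disease
crohn disease
ulcerative colitis
irritable bowel syndrome
peptic ulcer disease
gallstones
pancreatitis
anemia
sickle cell anemia
hemophilia
thalassemia
cystic fibrosis
muscular dystrophy
huntington disease
down syndrome
marfan syndrome
neurofibromatosis
hearing loss
meniere disease
glaucoma
macular degeneration
cataracts
color blindness
cleft palate
spina bifida
scoliosis
psoriasis
eczema
vitiligo
endometriosis
polycystic ovary syndrome
infertility
miscarriage
preeclampsia
wind sucking
sleep apnea
restless leg syndrome
fibromyalgia
chronic fatigue syndrome
glucose intolerance
aneurysm
abdominal aortic aneurysm
deep vein thrombosis
varicose veins
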