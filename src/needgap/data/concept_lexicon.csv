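term,concept
chemo,Chemotherapy
chemotherapy,Chemotherapy
chemo brain,Chemo Brain
radiation,Radiation Therapy
rads,Radiation Therapy
taxol,Taxol
herceptin,Herceptin
tamoxifen,Tamoxifen
arimidex,Arimidex
mastectomy,Mastectomy
double mastectomy,Double Mastectomy
lumpectomy,Lumpectomy
reconstruction,Breast Reconstruction
biopsy,Biopsy
mammogram,Mammography
mri,MRI
scan,Imaging Scan
ultrasound,Ultrasound
tumor,Tumor
lump,Lump
cancer,Cancer
breast cancer,Breast Cancer
triple negative,Triple Negative Breast Cancer
metastatic,Metastasis
stage,Cancer Stage
recurrence,Recurrence
remission,Remission
prognosis,Prognosis
diagnosis,Diagnosis
diagnosed,Diagnosis
oncologist,Oncologist
surgeon,Surgeon
nurse,Nurse
surgery,Surgery
implant,Breast Implant
port,Chemotherapy Port
hormone therapy,Hormone Therapy
clinical trial,Clinical Trial
treatment,Treatment
treatments,Treatment
side effect,Side Effects
side effects,Side Effects
side-effects,Side Effects
pain,Pain
sore,Soreness
soreness,Soreness
tired,Fatigue
fatigue,Fatigue
exhausted,Fatigue
swelling,Swelling
lymphedema,Lymphedema
nausea,Nausea
vomiting,Vomiting
numbness,Numbness
neuropathy,Neuropathy
tingling,Tingling
hair,Hair
hair loss,Hair Loss
bald,Hair Loss
wig,Wig
prosthesis,Prosthesis
hot flashes,Hot Flashes
headache,Headache
itching,Itching
rash,Rash
appetite,Appetite
weight,Body Weight
blood pressure,Blood Pressure
bowel,Bowel
swallowing,Swallowing
trouble swallowing,Swallowing Difficulty
insomnia,Insomnia
sleep,Sleep
scared,Fear
fear,Fear
afraid,Fear
anxiety,Anxiety
anxious,Anxiety
worry,Worry
worried,Worry
stress,Stress
depressed,Depression
depression,Depression
sad,Sadness
sadness,Sadness
crying,Crying
cry,Crying
mood,Mood
panic,Panic
hope,Hope
feel,Feeling
feelings,Feeling
exercise,Exercise
walking,Walking
yoga,Yoga
diet,Diet
nutrition,Nutrition
vitamins,Vitamins
supplements,Supplements
meditation,Meditation
hydration,Hydration
wellness,Wellness
shampoo,Shampoo
massage,Massage
husband,Family
wife,Family
daughter,Family
son,Family
sister,Family
mother,Family
family,Family
friend,Friend
friends,Friend
grandchildren,Family
married,Marital Status
retired,Employment
job,Employment
work,Employment
teacher,Employment
age,Age
years old,Age
insurance,Insurance
coverage,Insurance
medicare,Insurance
finances,Finances
money,Finances
bills,Finances
billing,Finances
paperwork,Paperwork
appointment,Appointment
pharmacy,Pharmacy
parking,Parking
travel,Travel
website,Website
site,Website
book,Book
books,Book
brochure,Brochure
pamphlet,Brochure
booklet,Brochure
article,Article
blog,Blog
podcast,Podcast
hotline,Hotline
library,Library
support group,Support Group
groups,Support Group
research,Research
mayo,Mayo Clinic
doctor,Physician
help,Help
look,Look
looking,Look
experience,Experience
normal,Normal
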