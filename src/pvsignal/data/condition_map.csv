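condition,pt
arrhythmias,Arrhythmia
arrhythmias,Arrhythmia supraventricular
arrhythmias,Atrial fibrillation
arrhythmias,Atrial flutter
arrhythmias,Atrial tachycardia
arrhythmias,Atrioventricular block
arrhythmias,Bradycardia
arrhythmias,Supraventricular tachycardia
heart_failure,Cardiac arrest
heart_failure,Cardiac Tamponade
heart_failure,Cardiac ventricular disorder
heart_failure,Cardiogenic shock
heart_failure,Coronary artery disease
heart_failure,Left ventricular dysfunction
heart_failure,Right ventricular dysfunction
cardiomyopathy,Cardiac Hypertrophy
cardiomyopathy,Cardiomyopathy
cardiomyopathy,Cardiotoxicity
cardiomyopathy,Ischaemic cardiomyopathy
myocardial_infarction,Acute coronary syndrome
myocardial_infarction,Acute myocardial infarction
myocardial_infarction,Angina pectoris
myocardial_infarction,Angina unstable
myocardial_infarction,Arterio-spasm coronary
myocardial_infarction,Kounis syndrome
myocardial_infarction,Prinzmetal angina
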