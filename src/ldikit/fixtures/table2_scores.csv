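zone,province,ldi,health_level,medical_capabilities,disease_prevention_and_control,ecological_environment,health_expenditure,health_industry
high,Beijing,100.00,100.00,100.00,100.00,97.13,100.00,100.00
high,Shanghai,91.39,94.03,96.41,100.00,76.58,78.45,88.82
high,Guangdong,87.76,100.00,72.95,73.89,95.29,59.15,99.99
high,Zhejiang,84.95,94.66,100.00,90.27,94.01,55.40,60.63
high,Jiangsu,84.57,92.71,93.95,97.07,83.13,49.27,70.61
medium-to-high,Shandong,83.12,96.75,84.39,88.66,90.48,57.02,61.98
medium-to-high,Tianjin,82.75,98.02,100.00,95.54,76.41,63.35,42.79
medium-to-high,Hubei,77.63,83.18,85.28,84.81,85.05,55.55,62.35
medium-to-high,Henan,77.05,89.14,75.08,82.95,81.84,52.31,61.81
medium-to-high,Jilin,75.89,79.65,99.80,97.82,83.05,62.14,33.53
medium-to-high,Shaanxi,75.69,92.96,90.96,96.16,82.44,58.23,19.45
medium-to-high,Ningxia,75.57,100.00,87.46,100.00,68.43,50.32,17.46
medium,Jiangxi,74.36,99.10,83.01,70.30,99.93,45.78,26.76
medium,Heilongjiang,74.29,75.36,99.75,96.00,87.91,63.10,30.94
medium,Fujian,74.26,97.67,77.12,81.88,100.00,46.21,23.79
medium,Hebei,72.97,91.51,65.97,89.58,88.06,53.89,32.71
medium,Anhui,72.62,86.95,87.73,65.40,87.00,39.73,49.55
medium,Hunan,72.12,94.20,80.48,54.82,91.79,51.38,39.41
medium,Hainan,71.74,96.68,94.67,62.41,96.87,61.21,6.53
medium,Liaoning,71.14,75.86,100.00,82.62,86.57,52.45,30.09
medium,Xinjiang,70.81,99.84,92.27,67.83,66.49,53.23,13.54
medium,Sichuan,70.81,86.62,87.43,60.46,78.91,54.05,40.76
medium,Inner Mongolia,70.08,82.61,99.16,88.35,75.82,49.70,15.03
low-to-medium,Shanxi,69.01,85.54,78.66,83.60,66.49,57.24,25.56
low-to-medium,Chongqing,68.72,85.70,82.08,56.16,81.03,44.35,43.14
low-to-medium,Guizhou,67.51,91.85,93.16,55.25,88.22,39.41,15.71
low-to-medium,Yunnan,67.31,79.66,100.00,67.02,77.05,41.90,25.77
low-to-medium,Gansu,66.98,83.70,97.19,94.95,68.17,32.58,5.54
low,Guangxi,64.20,93.60,79.28,34.80,91.04,46.92,17.06
low,Qinghai,60.84,80.87,100.00,65.19,50.64,38.20,5.17
low,Tibet,54.75,46.55,75.21,100.00,54.01,62.84,9.97
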